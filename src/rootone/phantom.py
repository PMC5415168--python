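"""Synthetic soil-root μCT phantoms with exact ground truth.

The phantom emulates the imaging effects the segmentation pipeline must
survive on real scans of rooted soil columns:

* a soil matrix with air-filled spherical pores,
* root segments as capsules (cylinders with hemispherical caps, so
  junctions are watertight),
* genuine partial-volume boundary voxels, produced by rasterizing the
  phases on a supersampled grid and block-averaging down — a voxel
  straddling two phases receives the volume-weighted mean grey,
* additive Gaussian noise,
* per-scan grey drift with duplicated overlap slices
  (:func:`split_scans`), emulating sequential scans of one column.

Default greys follow the qualitative contrast ordering of rooted soil:
air ≪ root < soil, with the root:soil contrast much smaller than the
air:soil contrast, so a gradient-based mask removes air:soil interfaces
while root:soil interfaces survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, VolumeError
from .volume import BinaryVolume, Volume

logger = logging.getLogger(__name__)


@dataclass
class RootSegment:
    """A straight root segment: endpoints in mm (z, y, x), diameter in μm."""

    start_mm: tuple[float, float, float]
    end_mm: tuple[float, float, float]
    diameter_um: float


@dataclass
class PhantomSpec:
    """Parametric description of a synthetic soil-root column.

    Grey values sit on the 16-bit scale.  ``supersample`` is the per-axis
    subdivision used to rasterize phase boundaries (so each voxel is
    averaged from ``supersample**3`` sub-voxels).
    """

    dims_voxels: tuple[int, int, int]
    voxel_size_um: float
    root_segments: list[RootSegment] = field(default_factory=list)
    grey_soil: float = 30000.0
    grey_root: float = 22000.0
    grey_air: float = 5000.0
    pore_fraction: float = 0.05
    pore_radius_range_voxels: tuple[float, float] = (2.0, 4.0)
    noise_sd: float = 800.0
    supersample: int = 4
    rng_seed: int = 0

    def __post_init__(self):
        if not self.voxel_size_um > 0:
            raise GeometryError("voxel_size_um must be positive")
        if not 0 <= self.pore_fraction < 0.5:
            raise GeometryError("pore_fraction must be in [0, 0.5)")
        if self.supersample < 2:
            raise GeometryError("supersample must be >= 2")
        if self.noise_sd < 0:
            raise GeometryError("noise_sd must be non-negative")
        for seg in self.root_segments:
            if seg.diameter_um <= 0:
                raise GeometryError("segment diameters must be positive")

    # -- unit helpers (voxel units) -------------------------------------
    def _to_vox(self, point_mm) -> np.ndarray:
        return np.asarray(point_mm, dtype=np.float64) * 1000.0 / self.voxel_size_um

    def _radius_vox(self, seg: RootSegment) -> float:
        return seg.diameter_um / 2.0 / self.voxel_size_um


@dataclass
class GroundTruth:
    """Exact geometry-derived truth for a phantom."""

    root_mask: BinaryVolume
    segment_lengths_um: list[float]
    total_length_um: float
    branch_points_mm: list[tuple[float, float, float]]
    branch_angles_deg: list[float]
    root_fraction: np.ndarray = field(repr=False, default=None)


def _subsampled_axis(lo: int, hi: int, s: int) -> np.ndarray:
    """Sub-voxel centre coordinates for voxel indices [lo, hi), in voxel units."""
    idx = np.arange(lo, hi, dtype=np.float64)
    offs = (np.arange(s, dtype=np.float64) + 0.5) / s
    return (idx[:, None] + offs[None, :]).ravel()


def _occupancy_into(
    frac: np.ndarray, p0: np.ndarray, p1: np.ndarray, radius: float, s: int
) -> None:
    """Accumulate (max) the sub-voxel occupancy of a capsule into ``frac``.

    ``p0``/``p1`` and ``radius`` are in voxel units; a zero-length segment
    is a sphere.  Only the capsule's bounding box is rasterized.
    """
    dims = frac.shape
    lo = np.floor(np.minimum(p0, p1) - radius - 1).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + radius + 1).astype(int)
    lo = np.clip(lo, 0, dims)
    hi = np.clip(hi, 0, dims)
    if np.any(hi <= lo):
        return
    axes = [_subsampled_axis(lo[i], hi[i], s) for i in range(3)]
    zz = axes[0][:, None, None]
    yy = axes[1][None, :, None]
    xx = axes[2][None, None, :]

    v = p1 - p0
    l2 = float(np.dot(v, v))
    dz, dy, dx = zz - p0[0], yy - p0[1], xx - p0[2]
    if l2 == 0.0:
        d2 = dz * dz + dy * dy + dx * dx
    else:
        t = np.clip((dz * v[0] + dy * v[1] + dx * v[2]) / l2, 0.0, 1.0)
        d2 = (dz - t * v[0]) ** 2 + (dy - t * v[1]) ** 2 + (dx - t * v[2]) ** 2
    inside = d2 <= radius * radius
    nz, ny, nx = hi - lo
    sub = inside.reshape(nz, s, ny, s, nx, s).mean(axis=(1, 3, 5))
    box = frac[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.maximum(box, sub, out=box)


def _root_fraction(spec: PhantomSpec) -> np.ndarray:
    frac = np.zeros(spec.dims_voxels, dtype=np.float64)
    for seg in spec.root_segments:
        _occupancy_into(
            frac,
            spec._to_vox(seg.start_mm),
            spec._to_vox(seg.end_mm),
            spec._radius_vox(seg),
            spec.supersample,
        )
    return frac


def build_geometry(spec: PhantomSpec) -> GroundTruth:
    """Analytic ground truth: mask, centerline lengths, branch points/angles.

    Segment centerlines must lie inside the column.  Branch points are
    endpoints shared by two or more segments; their angles are computed
    pairwise from the segments' away-pointing direction vectors.  The root
    mask marks voxels with majority (≥ 50%) root occupancy at supersampled
    precision.
    """
    dims = np.asarray(spec.dims_voxels, dtype=np.float64)
    for seg in spec.root_segments:
        for pt in (seg.start_mm, seg.end_mm):
            p = spec._to_vox(pt)
            if np.any(p < 0) or np.any(p > dims):
                raise GeometryError(f"segment endpoint {pt} mm outside the column")

    lengths = [
        float(np.linalg.norm(spec._to_vox(s.end_mm) - spec._to_vox(s.start_mm)))
        * spec.voxel_size_um
        for s in spec.root_segments
    ]

    # junctions: endpoints shared between segments (within a small tolerance)
    endpoints: list[tuple[tuple[float, float, float], np.ndarray]] = []
    for seg in spec.root_segments:
        a = np.asarray(seg.start_mm, dtype=np.float64)
        b = np.asarray(seg.end_mm, dtype=np.float64)
        direction = b - a
        # both endpoints carry the segment's travel direction, so the angle
        # at a junction is measured between the parent's downstream heading
        # and the daughter branch's heading (the standard field convention)
        endpoints.append((tuple(a), direction))
        endpoints.append((tuple(b), direction))

    branch_points: list[tuple[float, float, float]] = []
    branch_angles: list[float] = []
    used: set[int] = set()
    for i, (pt_i, dir_i) in enumerate(endpoints):
        if i in used:
            continue
        group = [i]
        for j in range(i + 1, len(endpoints)):
            if j in used:
                continue
            if np.allclose(pt_i, endpoints[j][0], atol=1e-9):
                group.append(j)
        if len(group) > 1:
            used.update(group)
            branch_points.append(pt_i)
            for a_idx in range(len(group)):
                for b_idx in range(a_idx + 1, len(group)):
                    u = endpoints[group[a_idx]][1]
                    v = endpoints[group[b_idx]][1]
                    cos = np.clip(
                        np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)),
                        -1.0,
                        1.0,
                    )
                    branch_angles.append(float(np.degrees(np.arccos(cos))))

    frac = _root_fraction(spec)
    mask = BinaryVolume(frac >= 0.5, spec.voxel_size_um)
    return GroundTruth(
        root_mask=mask,
        segment_lengths_um=lengths,
        total_length_um=float(sum(lengths)),
        branch_points_mm=branch_points,
        branch_angles_deg=branch_angles,
        root_fraction=frac,
    )


def _place_pores(spec: PhantomSpec, rng: np.random.Generator):
    """Non-overlapping pore spheres by rejection sampling (centres, radii).

    Pores keep ≥ 2 voxels of clearance from every root capsule so the
    ground-truth root mask stays exact.  If the target pore fraction
    cannot be reached within the attempt budget a warning is logged.
    """
    dims = np.asarray(spec.dims_voxels, dtype=np.float64)
    target_vox = spec.pore_fraction * float(np.prod(dims))
    if target_vox <= 0:
        return np.empty((0, 3)), np.empty(0)
    r_lo, r_hi = spec.pore_radius_range_voxels
    mean_vol = 4.0 / 3.0 * np.pi * ((r_lo + r_hi) / 2.0) ** 3
    max_attempts = int(50 * np.ceil(target_vox / mean_vol)) + 100

    segs = [
        (spec._to_vox(s.start_mm), spec._to_vox(s.end_mm), spec._radius_vox(s))
        for s in spec.root_segments
    ]
    centres: list[np.ndarray] = []
    radii: list[float] = []
    placed_vox = 0.0
    for _ in range(max_attempts):
        if placed_vox >= target_vox:
            break
        r = float(rng.uniform(r_lo, r_hi))
        if np.any(dims < 2 * r):
            continue
        c = rng.uniform(r, dims - r)
        # clearance from the root system
        ok = True
        for p0, p1, seg_r in segs:
            v = p1 - p0
            l2 = float(np.dot(v, v))
            t = 0.0 if l2 == 0 else float(np.clip(np.dot(c - p0, v) / l2, 0.0, 1.0))
            if np.linalg.norm(c - (p0 + t * v)) <= r + seg_r + 2.0:
                ok = False
                break
        if not ok:
            continue
        if centres:
            d = np.linalg.norm(np.asarray(centres) - c, axis=1)
            if np.any(d <= np.asarray(radii) + r):
                continue
        centres.append(c)
        radii.append(r)
        placed_vox += 4.0 / 3.0 * np.pi * r**3
    if placed_vox < target_vox:
        logger.warning(
            "pore packing reached only %.1f%% of the target pore fraction",
            100.0 * placed_vox / target_vox,
        )
    return np.asarray(centres).reshape(-1, 3), np.asarray(radii)


def render(spec: PhantomSpec, truth: GroundTruth | None = None) -> Volume:
    """Rasterize a phantom to a 16-bit greyscale volume.

    Phases (root capsules, spherical pores, soil elsewhere) are resolved
    on the supersampled grid and block-averaged, producing genuine
    partial-volume voxels; Gaussian noise is then added.  Identical spec
    and seed give a bit-identical volume.
    """
    rng = np.random.default_rng(spec.rng_seed)
    f_root = (
        truth.root_fraction
        if truth is not None and truth.root_fraction is not None
        else _root_fraction(spec)
    )
    f_pore = np.zeros(spec.dims_voxels, dtype=np.float64)
    centres, radii = _place_pores(spec, rng)
    for c, r in zip(centres, radii):
        _occupancy_into(f_pore, c, c, float(r), spec.supersample)

    f_pore = np.minimum(f_pore, 1.0 - f_root)  # root wins where both claim a voxel
    grey = (
        f_root * spec.grey_root
        + f_pore * spec.grey_air
        + (1.0 - f_root - f_pore) * spec.grey_soil
    )
    if spec.noise_sd > 0:
        grey = grey + rng.normal(0.0, spec.noise_sd, size=grey.shape)
    grey = np.clip(np.floor(grey + 0.5), 0.0, 65535.0).astype(np.uint16)
    return Volume(grey, spec.voxel_size_um)


def split_scans(
    volume: Volume,
    n_scans: int,
    overlap_slices: int,
    drifts: list[float],
) -> list[Volume]:
    """Cut a column into sequential sub-scans with duplicated overlap slices.

    Scan *i* covers its share of the depth plus ``overlap_slices``
    duplicated slices from the next scan's territory, and its grey values
    receive the additive drift ``drifts[i]`` (clipped/rounded for integer
    volumes).  With ``n_scans=1`` and zero drift the input is returned
    unchanged.
    """
    if n_scans < 1:
        raise VolumeError("n_scans must be >= 1")
    if len(drifts) != n_scans:
        raise VolumeError("need exactly one drift per scan")
    depth = volume.shape[0]
    bounds = [round(i * depth / n_scans) for i in range(n_scans + 1)]
    if n_scans > 1:
        if overlap_slices < 1:
            raise VolumeError("overlap_slices must be positive")
        if any(
            bounds[i + 1] + overlap_slices > depth for i in range(n_scans - 1)
        ) or any(
            overlap_slices >= bounds[i + 1] - bounds[i] for i in range(n_scans)
        ):
            raise VolumeError("overlap too large for the scan depths")

    scans = []
    for i in range(n_scans):
        stop = bounds[i + 1] + (overlap_slices if i < n_scans - 1 else 0)
        sub = volume.data[bounds[i]:stop].astype(np.float64) + drifts[i]
        if volume.data.dtype.kind == "u":
            info = np.iinfo(volume.data.dtype)
            sub = np.clip(np.floor(sub + 0.5), info.min, info.max).astype(
                volume.data.dtype
            )
        else:
            sub = sub.astype(volume.data.dtype)
        scans.append(Volume(sub, volume.voxel_size_um))
    return scans


def demo_spec(seed: int = 0) -> PhantomSpec:
    """A small branched demo phantom (taproot with one lateral)."""
    vs = 65.0
    dims = (96, 64, 64)
    mm = lambda zyx: tuple(c * vs / 1000.0 for c in zyx)
    return PhantomSpec(
        dims_voxels=dims,
        voxel_size_um=vs,
        root_segments=[
            RootSegment(mm((6, 32, 32)), mm((88, 32, 32)), diameter_um=6 * vs),
            RootSegment(mm((40, 32, 32)), mm((70, 56, 32)), diameter_um=4 * vs),
        ],
        rng_seed=seed,
    )
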