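"""Greyscale-to-binary root segmentation.

The processing chain turns a normalized, stitched greyscale column into a
single connected binary root system:

upsample ×2 → 2-D Sobel gradient → partial-volume (PVE) mask → bilevel
threshold → 3×3×3 median → optional 3-D erosion → seeded connectivity
extraction → 2×2×2 max re-binning back to the original voxel grid.

The ×2 resize gives fine roots enough voxels to survive the median and
erosion filters without fragmenting.  The Sobel+isodata mask removes the
sharp-gradient voxels at air:soil boundaries whose averaged grey values
mimic root tissue, while the gentler gradients at root:soil interfaces
pass through.  The seeded extraction then keeps exactly the connected
component containing a user-chosen voxel inside the root system.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateDistributionError, SeedError, VolumeError
from .normalization import align_peaks, find_overlap
from .volume import BinaryVolume, Volume

logger = logging.getLogger(__name__)

UPSAMPLE_FACTOR = 2


@dataclass
class SegmentationParams:
    """User-set parameters of the segmentation chain.

    ``root_grey_lo``/``root_grey_hi`` bound the root grey-value range
    (inclusive on both ends).  ``seed_voxel`` is given at the *original*
    (pre-resize) resolution and is scaled internally.  ``connectivity``
    selects the region-growing neighbourhood (6, 18 or 26).
    ``erosion_structure`` is ``"cross"`` (digital ball of diameter 3, the
    default) or ``"cube"`` (full 3×3×3).
    """

    root_grey_lo: float
    root_grey_hi: float
    seed_voxel: tuple[int, int, int]
    erosion_iterations: int = 0
    connectivity: int = 26
    erosion_structure: str = "cross"
    sanity_fraction: float = 0.05

    def __post_init__(self):
        if not self.root_grey_lo < self.root_grey_hi:
            raise VolumeError("root_grey_lo must be below root_grey_hi")
        if self.erosion_iterations < 0:
            raise VolumeError("erosion_iterations must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise VolumeError("connectivity must be 6, 18 or 26")
        if self.erosion_structure not in ("cross", "cube"):
            raise VolumeError("erosion_structure must be 'cross' or 'cube'")


@dataclass
class NormalizationOptions:
    """Peak-alignment and stitching settings for multi-scan input."""

    target_grey: float | None = None  # default: first scan's detected peak
    n_bins: int = 1024
    smooth_width: int = 5
    search_window: tuple[float, float] | None = None
    max_overlap: int = 20
    min_similarity: float = 0.9


@dataclass
class PveMask:
    """Mask of partial-volume voxels (True = excluded from root candidates)."""

    data: np.ndarray
    threshold_used: float

    def excluded_count(self) -> int:
        return int(self.data.sum())


def upsample2x(volume: Volume) -> Volume:
    """Double every dimension by linear interpolation (8× the voxel count).

    Output sample ``j`` sits at input coordinate ``j / 2`` (origin-aligned):
    even samples copy the grid values, odd samples are midpoints of
    neighbours, and the final odd sample clamps to the last grid value.
    The voxel size halves; a constant volume stays constant.  Output is
    ``float32`` to keep interpolated midpoints exact.
    """
    data = volume.data.astype(np.float32)
    for axis in range(3):
        n = data.shape[axis]
        shape = list(data.shape)
        shape[axis] = 2 * n
        out = np.empty(shape, dtype=np.float32)
        src = np.moveaxis(data, axis, 0)
        dst = np.moveaxis(out, axis, 0)
        dst[0::2] = src
        dst[1:-1:2] = 0.5 * (src[:-1] + src[1:])
        dst[-1] = src[-1]  # clamp beyond the last grid point
        data = out
    return Volume(data, volume.voxel_size_um / 2.0)


def sobel_edges2d(volume: Volume) -> Volume:
    """Per-slice Sobel gradient magnitude ``sqrt(Gx² + Gy²)``.

    Uses the standard 3×3 kernel pair on each z-slice independently (no
    smoothing across slices) with edge replication at borders.  An ideal
    in-slice step of height h yields magnitude 4h on the columns adjacent
    to the step; a linear ramp of slope s yields 8s in the interior.
    """
    if volume.shape[1] < 3 or volume.shape[2] < 3:
        raise VolumeError("each slice must be at least 3x3 for the Sobel kernel")
    d = volume.data.astype(np.float64)
    smooth = np.array([1.0, 2.0, 1.0])
    deriv = np.array([1.0, 0.0, -1.0])
    gx = ndimage.correlate1d(d, smooth, axis=1, mode="nearest")
    gx = ndimage.correlate1d(gx, deriv, axis=2, mode="nearest")
    gy = ndimage.correlate1d(d, smooth, axis=2, mode="nearest")
    gy = ndimage.correlate1d(gy, deriv, axis=1, mode="nearest")
    return Volume(np.hypot(gx, gy).astype(np.float32), volume.voxel_size_um)


def isodata_threshold(values, max_iter: int = 500) -> float:
    """Iterative intermeans (isodata) threshold.

    Finds the fixed point ``T = (mean(values <= T) + mean(values > T)) / 2``
    starting from the midrange, stopping when the update falls below half a
    grey level.
    """
    data = values.data if isinstance(values, Volume) else np.asarray(values)
    flat = data.ravel().astype(np.float64)
    lo, hi = float(flat.min()), float(flat.max())
    if lo == hi:
        raise DegenerateDistributionError(
            "degenerate distribution: all values identical"
        )
    t = 0.5 * (lo + hi)
    for _ in range(max_iter):
        below = flat <= t
        m_lo = flat[below].mean() if below.any() else lo
        m_hi = flat[~below].mean() if not below.all() else hi
        t_new = 0.5 * (m_lo + m_hi)
        if abs(t_new - t) < 0.5:
            return float(t_new)
        t = t_new
    return float(t)


def pve_mask(gradient: Volume) -> PveMask:
    """Mask voxels whose Sobel gradient exceeds the isodata threshold.

    These are the sharp air:soil boundary voxels whose partial-volume grey
    averages fall in the root range.  A constant (e.g. all-zero) gradient
    yields an empty mask by convention rather than an error.
    """
    g = gradient.data
    if float(g.min()) == float(g.max()):
        return PveMask(np.zeros(g.shape, dtype=bool), threshold_used=float(g.max()))
    t = isodata_threshold(gradient)
    return PveMask(g > t, threshold_used=t)


def bilevel_threshold(
    volume: Volume, params: SegmentationParams, mask: PveMask | None = None
) -> BinaryVolume:
    """Keep voxels inside the root grey range (inclusive) and outside the mask."""
    fg = (volume.data >= params.root_grey_lo) & (volume.data <= params.root_grey_hi)
    if mask is not None:
        if mask.data.shape != volume.shape:
            raise VolumeError("PVE mask and volume dimensions differ")
        fg &= ~mask.data
    return BinaryVolume(fg, volume.voxel_size_um)


def median3d(binary: BinaryVolume) -> BinaryVolume:
    """3×3×3 median filter (27-neighbourhood majority vote, edge replication).

    Removes small-scale structures — isolated voxels, thin tabs connecting
    roots to nearby pores — while large structures remain intact.
    """
    mean = ndimage.uniform_filter(
        binary.data.astype(np.float32), size=3, mode="nearest"
    )
    return BinaryVolume(mean * 27.0 > 13.5, binary.voxel_size_um)


def _erosion_structure(kind: str) -> np.ndarray:
    if kind == "cross":
        return ndimage.generate_binary_structure(3, 1)  # centre + 6 face nbrs
    return np.ones((3, 3, 3), dtype=bool)


def erode3d(
    binary: BinaryVolume, iterations: int, structure: str = "cross"
) -> BinaryVolume:
    """Morphological erosion with a diameter-3 kernel, applied ``iterations`` times.

    The default structuring element is the 6-face-neighbour cross (a
    digital ball of diameter 3); ``structure="cube"`` uses the full 3×3×3
    block.  Out-of-bounds neighbours count as foreground (edge
    replication), so the volume faces do not erode by themselves.
    ``iterations=0`` is the identity.
    """
    if iterations < 0:
        raise VolumeError("iterations must be >= 0")
    if iterations == 0:
        return BinaryVolume(binary.data.copy(), binary.voxel_size_um)
    eroded = ndimage.binary_erosion(
        binary.data,
        structure=_erosion_structure(structure),
        iterations=iterations,
        border_value=1,
    )
    return BinaryVolume(eroded, binary.voxel_size_um)


_CONNECTIVITY_STRUCTURE = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def extract_connected(
    binary: BinaryVolume, seed_voxel: tuple[int, int, int], connectivity: int = 26
) -> BinaryVolume:
    """Keep exactly the connected component containing the seed voxel.

    Raises :class:`~rootone.errors.SeedError` (with the nearest foreground
    voxel as a suggestion) when the seed lies on background.
    """
    seed = tuple(int(c) for c in seed_voxel)
    if len(seed) != 3 or any(
        not 0 <= c < n for c, n in zip(seed, binary.shape)
    ):
        raise SeedError(f"seed voxel {seed} outside volume bounds {binary.shape}")
    if not binary.data[seed]:
        nearest = None
        coords = np.argwhere(binary.data)
        if coords.size:
            d2 = ((coords - np.array(seed)) ** 2).sum(axis=1)
            nearest = tuple(int(c) for c in coords[int(np.argmin(d2))])
        raise SeedError(
            f"seed voxel {seed} is background; nearest foreground voxel: {nearest}",
            nearest_foreground=nearest,
        )
    labels, _ = ndimage.label(binary.data, structure=_CONNECTIVITY_STRUCTURE[connectivity])
    return BinaryVolume(labels == labels[seed], binary.voxel_size_um)


def bin_max(binary: BinaryVolume, factor: int = 2) -> BinaryVolume:
    """Re-bin 2×2×2 blocks to their maximum, restoring the original voxel size.

    A block is foreground if any of its voxels is foreground, so thin root
    structure survives the size reduction.  Odd dimensions are padded with
    background.
    """
    if factor != 2:
        raise VolumeError("only factor-2 re-binning is supported")
    data = binary.data
    pads = [(0, (-s) % 2) for s in data.shape]
    if any(p[1] for p in pads):
        data = np.pad(data, pads, mode="constant", constant_values=False)
    z, y, x = data.shape
    blocks = data.reshape(z // 2, 2, y // 2, 2, x // 2, 2)
    return BinaryVolume(blocks.any(axis=(1, 3, 5)), binary.voxel_size_um * 2.0)


def run_pipeline(
    scans: list[Volume],
    params: SegmentationParams,
    norm: NormalizationOptions | None = None,
) -> tuple[BinaryVolume, dict]:
    """Full segmentation chain from raw scan(s) to a binary root system.

    With multiple scans: peak alignment then sequential stitching first.
    The seed voxel (original resolution, relative to the stitched column)
    is scaled ×2 for the extraction stage.  Returns the re-binned binary
    root volume and a per-stage report (voxel counts, thresholds, shifts,
    overlaps, and a sanity flag when the extracted component is a
    suspiciously small fraction of the thresholded foreground).
    """
    norm = norm or NormalizationOptions()
    report: dict = {"stages": []}

    def log_stage(name, **info):
        report["stages"].append({"stage": name, **info})
        logger.info("stage %-18s %s", name, info)

    if len(scans) > 1:
        from .normalization import histogram, find_peak  # local to avoid cycle noise

        target = norm.target_grey
        if target is None:
            target = find_peak(
                histogram(scans[0], norm.n_bins), norm.search_window, norm.smooth_width
            ).peak_grey
        aligned = align_peaks(
            scans, target, norm.search_window, norm.smooth_width, norm.n_bins
        )
        log_stage("align_peaks", target_grey=float(target),
                  shifts=[float(s) for s in aligned.shifts])
        vol = aligned.volumes[0]
        overlaps = []
        for nxt in aligned.volumes[1:]:
            k, sim = find_overlap(vol, nxt, norm.max_overlap)
            if sim < norm.min_similarity:
                from .errors import StitchError

                raise StitchError(
                    f"stage stitch: no overlap detected (best similarity {sim:.3f})"
                )
            overlaps.append({"overlap": k, "similarity": sim})
            vol = Volume(
                np.concatenate([vol.data, nxt.data[k:]], axis=0), vol.voxel_size_um
            )
        log_stage("stitch", overlaps=overlaps, depth=vol.shape[0])
    else:
        vol = scans[0]

    if any(not 0 <= c < n for c, n in zip(params.seed_voxel, vol.shape)):
        raise SeedError(
            f"seed voxel {tuple(params.seed_voxel)} outside stitched volume {vol.shape}"
        )

    up = upsample2x(vol)
    log_stage("upsample2x", shape=list(up.shape))

    grad = sobel_edges2d(up)
    mask = pve_mask(grad)
    log_stage("pve_mask", threshold=float(mask.threshold_used),
              excluded_voxels=mask.excluded_count())

    bw = bilevel_threshold(up, params, mask)
    log_stage("bilevel_threshold", foreground=bw.foreground_count())

    med = median3d(bw)
    log_stage("median3d", foreground=med.foreground_count())

    ero = erode3d(med, params.erosion_iterations, params.erosion_structure)
    log_stage("erode3d", iterations=params.erosion_iterations,
              foreground=ero.foreground_count())

    seed_up = tuple(2 * int(c) for c in params.seed_voxel)
    ext = extract_connected(ero, seed_up, params.connectivity)
    pre = ero.foreground_count()
    frac = ext.foreground_count() / pre if pre else 0.0
    small = frac < params.sanity_fraction
    log_stage("extract_connected", seed=list(seed_up),
              foreground=ext.foreground_count(),
              component_fraction=frac, flag_small_component=small)
    if small:
        logger.warning(
            "extracted component holds only %.1f%% of thresholded foreground — "
            "check the seed voxel", 100 * frac,
        )

    out = bin_max(ext)
    log_stage("bin_max", foreground=out.foreground_count(), shape=list(out.shape))
    report["component_fraction"] = frac
    report["flag_small_component"] = small
    return out, report
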