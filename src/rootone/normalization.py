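"""Inter-scan grey normalization and axial stitching.

A tall soil column is imaged as several vertically adjoining scans.  Even
under identical acquisition settings, subtle compositional differences
drift the grey values assigned to each scan, so the same soil matrix lands
on different parts of the histogram.  Two steps restore a continuous
volume:

1. **Peak alignment** — detect a dominant localized histogram peak in each
   scan (the soil matrix peak in rooted soil columns) and shift each scan's
   grey values additively so the peaks coincide at a user-chosen grey.  A
   pure shift assumes the histogram variance is consistent between scans;
   no gain change is applied.
2. **Stitching** — sequential scans share a small band of duplicated
   slices.  The duplicate band is found by maximizing the mean normalized
   cross-correlation between the trailing slices of the upper scan and the
   leading slices of the lower scan, then removed, keeping the upper scan's
   copy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import PeakNotFoundError, StitchError, VolumeError
from .volume import Volume

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 1024
DEFAULT_SMOOTH_WIDTH = 5


@dataclass
class GreyHistogram:
    """Binned grey-value counts of a volume."""

    bin_edges: np.ndarray  # length n+1, strictly increasing
    counts: np.ndarray     # length n, non-negative integers

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class PeakInfo:
    """A localized histogram peak (grey value at the detected mode)."""

    peak_grey: float
    prominence: float
    search_window: tuple[float, float]


def histogram(volume: Volume, n_bins: int = DEFAULT_N_BINS) -> GreyHistogram:
    """Histogram of a volume over its own [min, max] grey range.

    Counts conserve the voxel count.  A constant volume occupies a single
    bin (numpy expands the degenerate range by ±0.5).
    """
    if n_bins < 2:
        raise VolumeError("n_bins must be >= 2")
    data = volume.data
    lo, hi = float(data.min()), float(data.max())
    counts, edges = np.histogram(data, bins=n_bins, range=(lo, hi))
    return GreyHistogram(bin_edges=edges, counts=counts)


def _smooth(counts: np.ndarray, width: int) -> np.ndarray:
    if width % 2 != 1 or width < 1:
        raise VolumeError("smooth_width must be an odd positive integer")
    if width == 1:
        return counts.astype(np.float64)
    pad = width // 2
    padded = np.pad(counts.astype(np.float64), pad, mode="edge")
    kernel = np.full(width, 1.0 / width)
    return np.convolve(padded, kernel, mode="valid")


def find_peak(
    hist: GreyHistogram,
    search_window: tuple[float, float] | None = None,
    smooth_width: int = DEFAULT_SMOOTH_WIDTH,
) -> PeakInfo:
    """Highest local maximum of the moving-average-smoothed counts.

    Bins that dominate both neighbours (>=) qualify as local maxima; the
    first and last bins of the support qualify too unless the whole
    histogram is monotone, in which case there is no *localised* peak and
    :class:`~rootone.errors.PeakNotFoundError` is raised.  (The support
    edge matters in practice: in a noise-free volume the dominant phase
    can sit exactly at the grey maximum and hence in the last bin.)  Ties
    break toward the lower grey value.
    """
    centers = hist.bin_centers
    if search_window is None:
        search_window = (float(centers[0]), float(centers[-1]))
    lo, hi = search_window
    smoothed = _smooth(hist.counts, smooth_width)

    n = len(smoothed)
    is_max = np.zeros(n, dtype=bool)
    is_max[1:-1] = (smoothed[1:-1] >= smoothed[:-2]) & (
        smoothed[1:-1] >= smoothed[2:]
    )
    diffs = np.diff(smoothed)
    monotone = bool(np.all(diffs >= 0) or np.all(diffs <= 0))
    if not monotone:
        is_max[0] = smoothed[0] >= smoothed[1]
        is_max[-1] = smoothed[-1] >= smoothed[-2]
    candidates = np.flatnonzero(is_max)
    candidates = candidates[(centers[candidates] >= lo) & (centers[candidates] <= hi)]
    if candidates.size == 0:
        raise PeakNotFoundError(
            f"no localized histogram peak inside search window ({lo}, {hi})"
        )
    # highest smoothed count wins; np.argmax takes the first (= lowest grey) tie
    best = candidates[np.argmax(smoothed[candidates])]
    in_window = (centers >= lo) & (centers <= hi)
    prominence = float(smoothed[best] - smoothed[in_window].min())
    return PeakInfo(
        peak_grey=float(centers[best]),
        prominence=prominence,
        search_window=(float(lo), float(hi)),
    )


@dataclass
class AlignmentResult:
    """Aligned scans together with the additive shift applied to each."""

    volumes: list[Volume]
    shifts: list[float]
    peaks: list[PeakInfo]


def align_peaks(
    volumes: list[Volume],
    target_grey: float,
    search_window: tuple[float, float] | None = None,
    smooth_width: int = DEFAULT_SMOOTH_WIDTH,
    n_bins: int = DEFAULT_N_BINS,
) -> AlignmentResult:
    """Shift each scan's grey values so its histogram peak lands on ``target_grey``.

    The transform is purely additive (``data + (target - peak)``), which
    permutes histogram counts along the grey axis without re-weighting
    them.  Integer volumes receive an integer shift (the float shift
    rounded) and are clipped to the dtype range.
    """
    out, shifts, peaks = [], [], []
    for vol in volumes:
        peak = find_peak(histogram(vol, n_bins), search_window, smooth_width)
        shift = float(target_grey) - peak.peak_grey
        if vol.data.dtype.kind == "u":
            shift = float(np.round(shift))
            info = np.iinfo(vol.data.dtype)
            shifted = np.clip(
                vol.data.astype(np.int64) + int(shift), info.min, info.max
            ).astype(vol.data.dtype)
        else:
            shifted = vol.data + np.float32(shift)
        logger.info("align_peaks: peak %.1f -> %.1f (shift %+.1f)",
                    peak.peak_grey, target_grey, shift)
        out.append(Volume(shifted, vol.voxel_size_um))
        shifts.append(shift)
        peaks.append(peak)
    return AlignmentResult(volumes=out, shifts=shifts, peaks=peaks)


def _slice_ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two equally shaped slices."""
    x = a.astype(np.float64).ravel()
    y = b.astype(np.float64).ravel()
    x -= x.mean()
    y -= y.mean()
    sx, sy = x.std(), y.std()
    if sx == 0.0 and sy == 0.0:
        # two constant slices: identical content correlates perfectly
        return 1.0 if np.array_equal(a, b) else 0.0
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float((x * y).mean() / (sx * sy))


def find_overlap(
    volume_a: Volume, volume_b: Volume, max_overlap: int
) -> tuple[int, float]:
    """Best duplicate-slice count between the end of A and the start of B.

    Returns ``(k, similarity)`` where ``k`` maximizes the mean NCC between
    A's last k slices and B's first k slices.  Ties break toward the larger
    overlap.
    """
    if volume_a.shape[1:] != volume_b.shape[1:]:
        raise VolumeError("scans differ in row/col dimensions")
    if volume_a.voxel_size_um != volume_b.voxel_size_um:
        raise VolumeError("scans differ in voxel size")
    if not (1 <= max_overlap < min(volume_a.shape[0], volume_b.shape[0])):
        raise VolumeError("max_overlap must be positive and smaller than both depths")

    da = volume_a.shape[0]
    best_k, best_sim = 1, -np.inf
    for k in range(1, max_overlap + 1):
        sims = [
            _slice_ncc(volume_a.data[da - k + i], volume_b.data[i]) for i in range(k)
        ]
        sim = float(np.mean(sims))
        if sim >= best_sim:
            best_k, best_sim = k, sim
    return best_k, best_sim


def stitch(
    volume_a: Volume,
    volume_b: Volume,
    max_overlap: int,
    min_similarity: float = 0.9,
) -> Volume:
    """Concatenate two adjoining scans, removing the duplicated slice band.

    A's slices are kept inside the overlap.  Raises
    :class:`~rootone.errors.StitchError` when no candidate overlap reaches
    ``min_similarity``.
    """
    k, sim = find_overlap(volume_a, volume_b, max_overlap)
    if sim < min_similarity:
        raise StitchError(
            f"no overlap detected: best similarity {sim:.3f} < {min_similarity}"
        )
    logger.info("stitch: overlap %d slices (similarity %.4f)", k, sim)
    data = np.concatenate([volume_a.data, volume_b.data[k:]], axis=0)
    return Volume(data, volume_a.voxel_size_um)
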