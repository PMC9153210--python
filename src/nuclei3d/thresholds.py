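"""Automatic global threshold estimation for background elimination.

Two estimators are fused. The noise-band method assumes that background noise
occupies a narrow intensity band: for each candidate threshold fraction
``Th_i`` it counts voxels inside the open band
``(Th_i - N_Level) * I_Max < v < Th_i * I_Max`` and picks the candidate with
the largest count. The triangle method finds the histogram bin with maximal
perpendicular distance to the line joining the histogram peak and the far end
of its longer tail. The final first-pass threshold is the larger of the two,
hard-capped at the second-pass fraction (10% of ``I_Max`` by default), beyond
which thresholding starts to destroy nuclear structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stack_io import DegenerateVolumeError, IntensityVolume

DEFAULT_TH_GRID: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20)
DEFAULT_N_LEVEL: float = 0.05
DEFAULT_TH_INT2: float = 0.10


@dataclass
class ThresholdEstimate:
    """Outcome of global threshold estimation on one volume.

    ``th_int1`` (first pass) and ``th_int2`` (second pass) are fractions of
    ``i_max``; ``candidate_grid`` and ``vox_counts`` record the noise-band
    scan for inspection.
    """

    i_max: int
    th_m1: float
    th_m2: float
    th_int1: float
    th_int2: float
    n_level: float
    candidate_grid: tuple[float, ...]
    vox_counts: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if not 0 < self.th_int1 <= self.th_int2 <= 0.2:
            raise ValueError(
                f"expected 0 < th_int1 <= th_int2 <= 0.2, got "
                f"({self.th_int1}, {self.th_int2})"
            )


def _as_data(vol: IntensityVolume | np.ndarray) -> np.ndarray:
    return vol.data if isinstance(vol, IntensityVolume) else np.asarray(vol)


def noise_band_threshold(
    vol: IntensityVolume | np.ndarray,
    grid: tuple[float, ...] = DEFAULT_TH_GRID,
    n_level: float = DEFAULT_N_LEVEL,
) -> tuple[float, tuple[int, ...]]:
    """Noise-band threshold fraction plus the per-candidate voxel counts.

    Band bounds are strict on both sides. Ties in the maximal count are
    broken toward the smallest candidate (less aggressive background
    removal).
    """
    data = _as_data(vol)
    if n_level <= 0:
        raise ValueError("n_level must be positive")
    if any(not 0 < g <= 1 for g in grid):
        raise ValueError("grid candidates must lie in (0, 1]")
    i_max = float(data.max()) if data.size else 0.0
    if i_max == 0:
        raise DegenerateVolumeError("all-zero volume has no noise band")
    counts = []
    for th in grid:
        lo = (th - n_level) * i_max
        hi = th * i_max
        counts.append(int(np.count_nonzero((data > lo) & (data < hi))))
    order = np.argsort(grid, kind="stable")
    best = min((g for g in order), key=lambda j: (-counts[j], grid[j]))
    return float(grid[best]), tuple(counts)


def _histogram_bins(bit_depth: int) -> int:
    return 256 if bit_depth <= 8 else 4096


def triangle_threshold(
    vol: IntensityVolume | np.ndarray,
    nbins: int | None = None,
    cap: float = DEFAULT_TH_INT2,
) -> float:
    """Triangle-method threshold as a fraction of ``I_Max``, capped at ``cap``.

    A line is drawn from the histogram peak to the last non-empty bin of the
    longer tail; the threshold sits at the bin with maximal perpendicular
    distance to that line. Binning follows the native quantisation (256 bins
    for 8-bit data, 4096 otherwise).
    """
    data = _as_data(vol)
    if nbins is None:
        bit_depth = getattr(vol, "bit_depth", 8 if data.dtype.itemsize == 1 else 16)
        nbins = _histogram_bins(bit_depth)
    i_max = float(data.max()) if data.size else 0.0
    if i_max == 0 or data.min() == data.max():
        raise DegenerateVolumeError("constant volume has no triangle threshold")
    hist, edges = np.histogram(data, bins=nbins, range=(0, i_max))
    nonzero = np.flatnonzero(hist)
    first, last = nonzero[0], nonzero[-1]
    peak = int(np.argmax(hist))
    # pick the side with the longer tail
    if last - peak >= peak - first:
        end = last
    else:
        end = first
    if end == peak:
        return min(float(edges[peak + 1] / i_max), cap)
    lo, hi = (peak, end) if end > peak else (end, peak)
    idx = np.arange(lo, hi + 1)
    # perpendicular distance from (i, hist[i]) to the peak-end line
    x0, y0 = float(peak), float(hist[peak])
    x1, y1 = float(end), float(hist[end])
    num = np.abs((y1 - y0) * idx - (x1 - x0) * hist[lo : hi + 1] + x1 * y0 - y1 * x0)
    best = idx[int(np.argmax(num))]
    threshold_value = edges[best + 1]  # upper edge of the best bin
    return min(float(threshold_value / i_max), cap)


def estimate_thresholds(
    vol: IntensityVolume | np.ndarray,
    th_grid: tuple[float, ...] = DEFAULT_TH_GRID,
    n_level: float = DEFAULT_N_LEVEL,
    th_int2: float = DEFAULT_TH_INT2,
) -> ThresholdEstimate:
    """Fuse the noise-band and triangle estimators into the two-pass scheme.

    ``th_int1 = max(th_m1, th_m2)``, capped at ``th_int2`` — the background
    threshold must not exceed the second-pass fraction, past which nuclear
    structure is destroyed.
    """
    data = _as_data(vol)
    i_max = int(data.max()) if data.size else 0
    if i_max == 0:
        raise DegenerateVolumeError("cannot estimate thresholds on an empty volume")
    th_m1, counts = noise_band_threshold(vol, grid=th_grid, n_level=n_level)
    try:
        th_m2 = triangle_threshold(vol, cap=th_int2)
    except DegenerateVolumeError:
        th_m2 = th_int2
    th_int1 = min(max(th_m1, th_m2), th_int2)
    return ThresholdEstimate(
        i_max=i_max,
        th_m1=th_m1,
        th_m2=th_m2,
        th_int1=th_int1,
        th_int2=th_int2,
        n_level=n_level,
        candidate_grid=tuple(th_grid),
        vox_counts=counts,
    )
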