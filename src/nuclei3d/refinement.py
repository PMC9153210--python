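"""Upsampling of block-scale masks and intensity-based border refinement.

Nearest-neighbour upsampling of the block grid back to the original
resolution leaves every nucleus wrapped in a blocky contour several voxels
thick. The refinement step trims that contour at 1:1 scale: for each nucleus
the mean interior intensity ``NC_MeanInt`` is computed (excluding the surface
shell) and a shell voxel is kept only when its own intensity exceeds
``I_Th * NC_MeanInt``. Shell voxels can only be returned to background —
the mask never grows, and voxels on the boundary between two nuclei keep
their label (the rule decides nucleus-vs-background only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .stack_io import IntensityVolume, LabelVolume

I_TH_DEFAULT = 0.3
SHELL_DEPTH_DEFAULT = 3  # thickness (voxels) of the upsampled surface contour

log = logging.getLogger(__name__)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class RefinementParams:
    """Tunables of the border-refinement sweep.

    ``i_th`` is the surface-merge threshold fraction (values above ~0.3 start
    to eat into real nucleus volume; lower values change little).
    ``shell_depth`` is how many 26-connected erosion steps define the surface
    shell — it matches the thickness of the contour left by nearest-neighbour
    upsampling.
    """

    i_th: float = I_TH_DEFAULT
    shell_depth: int = SHELL_DEPTH_DEFAULT

    def __post_init__(self) -> None:
        if not 0 < self.i_th < 1:
            raise ValueError("i_th must lie in (0, 1)")
        if self.shell_depth < 1:
            raise ValueError("shell_depth must be >= 1")


def _upsample_nn(arr: np.ndarray, factors: tuple[int, int, int]) -> np.ndarray:
    for axis, f in enumerate(factors):
        if f != 1:
            arr = np.repeat(arr, f, axis=axis)
    return arr


def _fit_to_shape(arr: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Crop and/or edge-pad to the requested shape (odd-dimension remainders)."""
    arr = arr[tuple(slice(0, s) for s in shape)]
    pads = [(0, max(s - a, 0)) for s, a in zip(shape, arr.shape)]
    if any(p[1] for p in pads):
        arr = np.pad(arr, pads, mode="edge")
    return arr


def upsample_labels(
    labels: LabelVolume,
    scaled_shape: tuple[int, int, int],
    full_shape: tuple[int, int, int],
    block: int = 3,
) -> LabelVolume:
    """Two-stage nearest-neighbour upsampling of block-grid labels.

    First by ``block`` along every axis to the downscaled grid, then by 2 in
    XY to the original grid; each stage is cropped/edge-padded to the exact
    target shape.
    """
    grid = labels.labels
    expected = tuple(-(-s // block) for s in scaled_shape)
    if grid.shape != expected:
        raise ValueError(
            f"label grid shape {grid.shape} inconsistent with scaled shape "
            f"{scaled_shape} (expected {expected})"
        )
    at_scaled = _fit_to_shape(_upsample_nn(grid, (block, block, block)), scaled_shape)
    at_full = _fit_to_shape(_upsample_nn(at_scaled, (1, 2, 2)), full_shape)
    return LabelVolume(at_full.astype(np.int32))


def refine_surface(
    labels: LabelVolume,
    vol: IntensityVolume,
    params: RefinementParams | None = None,
) -> LabelVolume:
    """One intensity sweep over each nucleus' surface shell.

    The shell is the set of labelled voxels within ``shell_depth``
    26-connected steps of *background* (label 0) — voxels facing a
    neighbouring nucleus are interior for this purpose and are never
    reassigned. A nucleus whose interior would be empty is left unrefined.
    """
    params = params or RefinementParams()
    if labels.shape != vol.shape:
        raise ValueError("labels and intensity volume must share the same shape")
    arr = labels.labels
    if arr.max() == 0:
        return LabelVolume(arr.copy())
    background = arr == 0
    near_bg = ndimage.binary_dilation(
        background, structure=_STRUCT_26, iterations=params.shell_depth
    )
    shell_all = near_bg & ~background
    out = arr.copy()
    intensity = vol.data
    for sl, label_id in zip(ndimage.find_objects(arr), range(1, arr.max() + 1)):
        if sl is None:
            continue
        mask = arr[sl] == label_id
        shell = mask & shell_all[sl]
        interior = mask & ~shell
        if not interior.any():
            log.warning("nucleus %d has no interior; left unrefined", label_id)
            continue
        mean_int = float(intensity[sl][interior].mean())
        drop = shell & ~(intensity[sl] > params.i_th * mean_int)
        region = out[sl]
        region[drop] = 0
        # trimming a dim isthmus can disconnect a nucleus; keep the largest
        # 26-connected piece, crumbs go back to background
        remaining = region == label_id
        pieces, n = ndimage.label(remaining, structure=_STRUCT_26)
        if n > 1:
            sizes = ndimage.sum_labels(remaining, pieces, index=range(1, n + 1))
            keep = 1 + int(np.argmax(sizes))
            region[remaining & (pieces != keep)] = 0
    return LabelVolume(out)
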