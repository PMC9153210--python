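"""Reading and writing of 3D image stacks, label volumes and 2D ground-truth masks.

All grids use ``(z, y, x)`` index order, matching the page-major storage of
multi-page TIFF files. Physical voxel spacing is carried in nanometres, also
in ``(z, y, x)`` order; when a file carries no usable spacing metadata the
loader falls back to the acquisition spacing of the confocal dataset this
package targets (250 nm optical sections, 120 nm pixels).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage

#: Default physical voxel size in nm, (z, y, x).
DEFAULT_SPACING_NM: tuple[float, float, float] = (250.0, 120.0, 120.0)

_STRUCT_8CONN_2D = np.ones((3, 3), dtype=bool)


class UnsupportedFormatError(ValueError):
    """Raised for RGB/multi-channel pages or stacks with fewer than 3 planes."""


class DegenerateVolumeError(ValueError):
    """Raised when an operation receives an all-zero / constant volume."""


@dataclass
class IntensityVolume:
    """A 3D grayscale voxel grid with spacing metadata.

    Parameters
    ----------
    data:
        3D integer array indexed ``(z, y, x)``, non-negative.
    spacing:
        Physical voxel size per axis in nm, ``(z, y, x)``.
    bit_depth:
        Nominal bit depth of the acquisition (8-16).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING_NM
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise UnsupportedFormatError(
                f"expected a 3D (z, y, x) grid, got ndim={self.data.ndim}"
            )
        if any(s < 3 for s in self.data.shape):
            raise UnsupportedFormatError(
                f"every axis needs at least 3 voxels, got shape {self.data.shape}"
            )
        if not (8 <= self.bit_depth <= 16):
            raise ValueError(f"bit_depth must be in 8..16, got {self.bit_depth}")
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be non-negative")
        if self.data.size and self.data.max() > 2**self.bit_depth - 1:
            raise ValueError(
                f"intensity {self.data.max()} exceeds 2^{self.bit_depth}-1"
            )
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def i_max(self) -> int:
        return int(self.data.max())


@dataclass
class LabelVolume:
    """3D integer grid; 0 = background, k >= 1 = nucleus index."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D (z, y, x) grid")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def n_labels(self) -> int:
        return len(self.label_ids)

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def relabeled(self) -> "LabelVolume":
        """Return a copy with labels renumbered consecutively 1..K."""
        ids = self.label_ids
        lut = np.zeros(int(self.labels.max()) + 1, dtype=np.int32)
        lut[ids] = np.arange(1, len(ids) + 1, dtype=np.int32)
        return LabelVolume(lut[self.labels])


@dataclass
class GroundTruthLayer:
    """Expert ground truth for one designated optical section.

    ``mask`` is stored as a 2D per-nucleus label image: either loaded directly
    from a labelled file, or derived from a binary mask by 8-connected
    component labelling.
    """

    mask: np.ndarray
    layer_index: int
    nucleus_count: int = field(default=-1)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 2:
            raise ValueError("ground-truth mask must be 2D")
        if self.nucleus_count < 0:
            self.nucleus_count = len(self.label_ids)
        if self.nucleus_count != len(self.label_ids):
            raise ValueError("nucleus_count disagrees with mask components")

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.mask)
        return ids[ids > 0]

    def nucleus_mask(self, label_id: int) -> np.ndarray:
        return self.mask == label_id


def _spacing_from_tiff(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Best-effort spacing (nm) from ImageJ/resolution metadata, else None."""
    try:
        z = y = x = None
        meta = tif.imagej_metadata or {}
        unit = (meta.get("unit") or "").lower()
        factor = {"um": 1000.0, "micron": 1000.0, "µm": 1000.0, "nm": 1.0}.get(unit)
        if factor is None:
            return None
        if "spacing" in meta:
            z = float(meta["spacing"]) * factor
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if xres is not None and yres is not None:
            xr = xres.value[0] / xres.value[1]
            yr = yres.value[0] / yres.value[1]
            if xr > 0 and yr > 0:
                x = factor / xr
                y = factor / yr
        if z is not None and y is not None and x is not None:
            return (z, y, x)
    except Exception:
        pass
    return None


def read_stack(
    path: str | os.PathLike,
    default_spacing: Sequence[float] = DEFAULT_SPACING_NM,
) -> IntensityVolume:
    """Read a multi-page grayscale TIFF into an :class:`IntensityVolume`.

    Pages are stacked along Z in file order. Spacing is taken from metadata
    when present, else from ``default_spacing``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        spacing = _spacing_from_tiff(tif) or tuple(float(s) for s in default_spacing)
    if data.ndim == 2:
        raise UnsupportedFormatError("stack has fewer than 3 pages")
    if data.ndim != 3:
        raise UnsupportedFormatError(
            f"RGB or multi-channel TIFF is not supported (ndim={data.ndim})"
        )
    bit_depth = 8 if data.dtype.itemsize == 1 else 16
    return IntensityVolume(data=data, spacing=spacing, bit_depth=bit_depth)


def write_stack(vol: IntensityVolume, path: str | os.PathLike) -> None:
    """Write an intensity volume as a multi-page grayscale TIFF."""
    data = vol.data
    dtype = np.uint8 if vol.bit_depth <= 8 else np.uint16
    tifffile.imwrite(path, data.astype(dtype), photometric="minisblack")


def write_labels(vol: LabelVolume, path: str | os.PathLike) -> None:
    """Write a label volume as a 16-bit multi-page TIFF, one page per Z slice."""
    if vol.labels.size and vol.labels.max() > 65535:
        raise ValueError("more than 65535 labels cannot be stored in 16-bit TIFF")
    tifffile.imwrite(path, vol.labels.astype(np.uint16), photometric="minisblack")


def read_labels(path: str | os.PathLike) -> LabelVolume:
    """Read a label volume written by :func:`write_labels`."""
    data = tifffile.imread(path)
    if data.ndim != 3:
        raise UnsupportedFormatError("label volume must be a 3D multi-page TIFF")
    return LabelVolume(labels=data.astype(np.int32))


def read_ground_truth(path: str | os.PathLike, layer_index: int) -> GroundTruthLayer:
    """Load a 2D expert mask (PNG or TIFF) for one optical section.

    A binary image is converted to per-nucleus masks by 8-connected component
    labelling; an already-labelled image (one integer per nucleus) is used
    directly. The loader is deliberately format-tolerant.
    """
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:  # collapse an RGB(A) mask to one channel
        img = img[..., 0]
    if img.ndim != 2:
        raise UnsupportedFormatError("ground-truth mask must be a single 2D image")
    values = np.unique(img)
    positive = values[values > 0]
    if len(positive) <= 1:  # binary (possibly 0/255)
        labelled, _ = ndimage.label(img > 0, structure=_STRUCT_8CONN_2D)
        return GroundTruthLayer(mask=labelled.astype(np.int32), layer_index=layer_index)
    return GroundTruthLayer(mask=img.astype(np.int32), layer_index=layer_index)


def concatenate_stacks(stacks: Sequence[IntensityVolume]) -> IntensityVolume:
    """Merge stacks along the Z axis (Z lengths add, voxel values preserved).

    All stacks must share XY dimensions and spacing. Used to reproduce the
    stacked-specimen experiments on synthetic data.
    """
    if len(stacks) == 0:
        raise ValueError("need at least one stack")
    first = stacks[0]
    for s in stacks[1:]:
        if s.shape[1:] != first.shape[1:]:
            raise ValueError(
                f"XY shape mismatch: {s.shape[1:]} vs {first.shape[1:]}"
            )
        if s.spacing != first.spacing:
            raise ValueError("spacing mismatch between stacks")
    data = np.concatenate([s.data for s in stacks], axis=0)
    return IntensityVolume(
        data=data,
        spacing=first.spacing,
        bit_depth=max(s.bit_depth for s in stacks),
    )
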