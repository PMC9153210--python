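"""3D shape descriptors and single-nucleus vs. group classification.

A candidate structure is a single nucleus (``NC_S``) when it is compact —
solidity >= 0.95 and sphericity >= 0.85 — and its volume lies inside bounds
derived from the size of the (downscaled) volume; anything else is a group
(``NC_G``) that must be split. Sphericity uses a triangulated isosurface for
the surface area: counting exposed voxel faces overestimates a sphere's area
by ~1.5x, which would make the 0.85 threshold unreachable for true spheres.
Solidity rasterises the convex hull at grid resolution so that it stays a
voxel-count ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology

from .stack_io import LabelVolume

SOLID_THR_DEFAULT = 0.95
SPHER_THR_DEFAULT = 0.85
VOL_MIN_COEFF = 5e-6
VOL_MAX_COEFF = 2e-2

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

Classification = Literal["NC_S", "NC_G"]


@dataclass
class ShapeCriteria:
    """Thresholds of the single-nucleus test.

    ``vol_min``/``vol_max`` are in the voxel units of the grid on which
    structures are measured; :meth:`from_scaled_size` builds them from the
    total voxel count of the downscaled volume, :meth:`rescaled` converts
    them to another grid (e.g. block units, factor ``1/27``).
    """

    solid_thr: float = SOLID_THR_DEFAULT
    spher_thr: float = SPHER_THR_DEFAULT
    vol_min: float = 1.0
    vol_max: float = float("inf")

    def __post_init__(self) -> None:
        if not (0 < self.solid_thr <= 1 and 0 < self.spher_thr <= 1):
            raise ValueError("shape thresholds must lie in (0, 1]")
        if not self.vol_min < self.vol_max:
            raise ValueError("vol_min must be smaller than vol_max")

    @classmethod
    def from_scaled_size(
        cls,
        n_voxels: int,
        solid_thr: float = SOLID_THR_DEFAULT,
        spher_thr: float = SPHER_THR_DEFAULT,
        vol_min_coeff: float = VOL_MIN_COEFF,
        vol_max_coeff: float = VOL_MAX_COEFF,
    ) -> "ShapeCriteria":
        return cls(
            solid_thr=solid_thr,
            spher_thr=spher_thr,
            vol_min=vol_min_coeff * n_voxels,
            vol_max=vol_max_coeff * n_voxels,
        )

    def rescaled(self, voxel_factor: float) -> "ShapeCriteria":
        """Volume bounds converted to a grid whose voxels are ``1/voxel_factor``
        times larger (e.g. ``voxel_factor = 1/27`` for the 3x3x3 block grid)."""
        return ShapeCriteria(
            solid_thr=self.solid_thr,
            spher_thr=self.spher_thr,
            vol_min=self.vol_min * voxel_factor,
            vol_max=self.vol_max * voxel_factor,
        )


@dataclass
class NucleusRecord:
    """Morphometry of one 26-connected structure."""

    id: int
    vol: int
    vol_convex: int
    surf: float
    spher: float
    solid: float
    cls: Classification | None = None
    origin: tuple[int, int, int] = (0, 0, 0)  # bbox offset of the measured mask


def _convex_volume(mask: np.ndarray) -> int:
    """Voxel count of the rasterized convex hull (>= the mask's own count)."""
    coords = np.argwhere(mask)
    # qhull needs a full-rank simplex; degenerate sets are their own hull
    if len(coords) < 4 or np.linalg.matrix_rank(coords - coords[0]) < 3:
        return int(mask.sum())
    try:
        # offset_coordinates pads the hull outward by half a voxel, which
        # drops the solidity of a digital ball to ~0.91; the plain hull of
        # the voxel centres is exact for convex digitized shapes
        hull = morphology.convex_hull_image(mask, offset_coordinates=False)
        return max(int(hull.sum()), int(mask.sum()))
    except Exception:
        return int(mask.sum())


def _mesh_surface_area(mask: np.ndarray) -> float:
    padded = np.pad(mask.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    return float(measure.mesh_surface_area(verts, faces))


def measure_structure(mask: np.ndarray, structure_id: int = 0) -> NucleusRecord:
    """Measure volume, convex volume, surface, sphericity and solidity.

    ``mask`` is a binary 3D array holding one 26-connected structure. The
    mask is cropped to its bounding box before meshing; ``origin`` records
    the offset.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3 or not mask.any():
        raise ValueError("mask must be a non-empty 3D binary array")
    slices = ndimage.find_objects(mask.astype(np.uint8))[0]
    cropped = mask[slices]
    vol = int(cropped.sum())
    vol_convex = _convex_volume(cropped)
    surf = _mesh_surface_area(cropped)
    spher = float((36.0 * np.pi * vol**2) ** (1.0 / 3.0) / surf)
    solid = vol / vol_convex
    return NucleusRecord(
        id=structure_id,
        vol=vol,
        vol_convex=vol_convex,
        surf=surf,
        spher=spher,
        solid=solid,
        origin=tuple(s.start for s in slices),
    )


def classify_structure(rec: NucleusRecord, crit: ShapeCriteria) -> Classification:
    """``NC_S`` iff solid, spherical and inside the volume bounds, else ``NC_G``."""
    single = (
        rec.solid >= crit.solid_thr
        and rec.spher >= crit.spher_thr
        and crit.vol_min <= rec.vol < crit.vol_max
    )
    return "NC_S" if single else "NC_G"


def filter_small_debris(labels: LabelVolume, vol_min: float) -> LabelVolume:
    """Remove components smaller than ``vol_min`` voxels (residual background)."""
    arr = labels.labels
    if arr.max() == 0:
        return LabelVolume(arr.copy())
    ids, counts = np.unique(arr[arr > 0], return_counts=True)
    keep = np.zeros(int(arr.max()) + 1, dtype=bool)
    keep[ids[counts >= vol_min]] = True
    out = np.where(keep[arr], arr, 0)
    return LabelVolume(out).relabeled()


def records_to_dataframe(records: list[NucleusRecord]) -> pd.DataFrame:
    """Per-nucleus morphometry table (id, vol, surf, spher, solid, cls)."""
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "vol": r.vol,
                "vol_convex": r.vol_convex,
                "surf": r.surf,
                "spher": r.spher,
                "solid": r.solid,
                "cls": r.cls,
            }
            for r in records
        ]
    )
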