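"""End-to-end segmentation pipeline.

Control flow: downscale XY by 50% → build the 3x3x3 block grid → estimate the
first-pass threshold from the intensity histogram → classify blocks →
26-connected components → per component: single-nucleus test; groups are
split by iterative seeding + watershed; groups that yield one seed yet exceed
the volume ceiling are locally re-thresholded at the second-pass fraction and
re-enter classification; whatever still cannot be divided is accepted
unsplit. Residual debris below the volume floor is removed, the block-scale
labels are upsampled to the original grid and (optionally) border-refined by
local intensity.

The segmentation path contains no randomness: identical input and
configuration give bitwise-identical label volumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import yaml
from scipy import ndimage

from . import blocks as _blocks
from . import morphometry as _morpho
from . import refinement as _refine
from . import splitting as _split
from . import thresholds as _thresh
from .stack_io import DegenerateVolumeError, IntensityVolume, LabelVolume
from .morphometry import NucleusRecord, ShapeCriteria
from .thresholds import ThresholdEstimate

log = logging.getLogger(__name__)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PipelineConfig:
    """Every named parameter of the pipeline, with its default."""

    n_level: float = 0.05
    th_grid: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20)
    th_int2: float = 0.10
    solid_thr: float = 0.95
    spher_thr: float = 0.85
    vol_min_coeff: float = 5e-6
    vol_max_coeff: float = 2e-2
    dist_min_factor: float = 0.5
    dist_step: float = 0.2
    i_th: float = 0.3
    scale_xy: float = 0.5
    block: int = 3
    refine: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "th_grid" in raw:
            raw["th_grid"] = tuple(raw["th_grid"])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        data = asdict(self)
        data["th_grid"] = list(data["th_grid"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class Provenance:
    """How one accepted nucleus came to be."""

    label: int
    pass_no: int
    case: Literal["single", "indivisible", "split", "unsplittable"]
    parent_seeds: int = 1


@dataclass
class SegmentationResult:
    labels: LabelVolume
    records: list[NucleusRecord]
    thresholds: ThresholdEstimate | None
    provenance: list[Provenance] = field(default_factory=list)
    block_labels: LabelVolume | None = None

    @property
    def n_nuclei(self) -> int:
        return len(self.records)


def rethreshold_group(
    group_mask: np.ndarray, means: np.ndarray, i_max: float, th_int2: float
) -> list[np.ndarray]:
    """Re-threshold one group's block means at the second-pass fraction.

    The threshold is local (applied only under the group's mask) but uses the
    global ``i_max``. Returns the 26-connected components of what survives;
    an empty list means the group dissolves entirely at the higher threshold.
    """
    sub = group_mask & (means > i_max * th_int2)
    if not sub.any():
        return []
    lab, n = ndimage.label(sub, structure=_STRUCT_26)
    return [lab == comp for comp in range(1, n + 1)]


class _Segmenter:
    """Holds shared state (grid, thresholds, criteria) during one run."""

    def __init__(self, grid: _blocks.BlockGrid, est: ThresholdEstimate, cfg: PipelineConfig):
        self.grid = grid
        self.est = est
        self.cfg = cfg
        scaled_size = int(np.prod(grid.scaled_shape))
        self.crit_scaled = ShapeCriteria.from_scaled_size(
            scaled_size,
            solid_thr=cfg.solid_thr,
            spher_thr=cfg.spher_thr,
            vol_min_coeff=cfg.vol_min_coeff,
            vol_max_coeff=cfg.vol_max_coeff,
        )
        # structures are measured on the block grid: convert volume bounds
        self.crit_blocks = self.crit_scaled.rescaled(1.0 / cfg.block**3)
        self.final = np.zeros(grid.means.shape, dtype=np.int32)
        self.records: list[NucleusRecord] = []
        self.provenance: list[Provenance] = []
        self._next = 1

    # -- acceptance -------------------------------------------------------
    def accept(self, mask: np.ndarray, pass_no: int, case: str, n_seeds: int = 1) -> None:
        rec = _morpho.measure_structure(mask, structure_id=self._next)
        rec.cls = "NC_S"
        self.final[mask] = self._next
        self.records.append(rec)
        self.provenance.append(
            Provenance(label=self._next, pass_no=pass_no, case=case, parent_seeds=n_seeds)
        )
        self._next += 1

    # -- per-component routine -------------------------------------------
    def process(self, mask: np.ndarray, pass_no: int) -> None:
        rec = _morpho.measure_structure(mask)
        if _morpho.classify_structure(rec, self.crit_blocks) == "NC_S":
            self.accept(mask, pass_no, "single")
            return
        # group: try to divide via seeds + watershed
        dmap = _split.modified_distance_map(mask)
        seeds = _split.generate_seeds(
            dmap, factor=self.cfg.dist_min_factor, step=self.cfg.dist_step
        )
        log.debug(
            "pass %d cluster vol=%d seeds=%d", pass_no, rec.vol, len(seeds)
        )
        if len(seeds) >= 2:
            parts = _split.split_cluster(mask, seeds, dmap=dmap)
            for pid in parts.label_ids:
                self.accept(parts.labels == pid, pass_no, "split", n_seeds=len(seeds))
            return
        oversized = rec.vol >= self.crit_blocks.vol_max
        if not oversized:
            self.accept(mask, pass_no, "indivisible")
            return
        if pass_no == 1:
            self.second_pass(mask)
        else:
            self.accept(mask, pass_no, "unsplittable")

    def second_pass(self, group_mask: np.ndarray) -> None:
        """Local re-thresholding of an oversized, indivisible group.

        Block means under the group mask are re-thresholded at
        ``Th_Int2 * I_Max`` (global maximum, local region); the shrunken
        components re-enter classification and splitting. If nothing
        survives, the group is accepted unsplit.
        """
        parts = rethreshold_group(
            group_mask, self.grid.means, self.est.i_max, self.est.th_int2
        )
        if not parts:
            self.accept(group_mask, 1, "unsplittable")
            return
        for part in parts:
            self.process(part, pass_no=2)


def segment(vol: IntensityVolume, cfg: PipelineConfig | None = None) -> SegmentationResult:
    """Run the full segmentation on one intensity volume."""
    cfg = cfg or PipelineConfig()
    scaled = _blocks.downscale_xy(vol, factor=cfg.scale_xy)
    i_max = scaled.i_max
    if i_max == 0:
        log.warning("all-zero volume: returning an empty result")
        return SegmentationResult(
            labels=LabelVolume(np.zeros(vol.shape, dtype=np.int32)),
            records=[],
            thresholds=None,
        )
    try:
        est = _thresh.estimate_thresholds(
            scaled, th_grid=cfg.th_grid, n_level=cfg.n_level, th_int2=cfg.th_int2
        )
    except DegenerateVolumeError:
        log.warning("degenerate volume: returning an empty result")
        return SegmentationResult(
            labels=LabelVolume(np.zeros(vol.shape, dtype=np.int32)),
            records=[],
            thresholds=None,
        )
    grid = _blocks.classify_blocks(
        _blocks.block_means(scaled, block=cfg.block), i_max, est.th_int1
    )
    # a threshold that removes (almost) nothing means there is no bright
    # structure over background at all — an empty or noise-only field
    fg_fraction = float(grid.result.mean())
    if fg_fraction > 0.9:
        grid2 = _blocks.classify_blocks(grid, i_max, est.th_int2)
        if float(grid2.result.mean()) > 0.9:
            log.warning(
                "thresholding removes <10%% of the field (fg=%.2f): "
                "no separable structures, returning an empty result",
                fg_fraction,
            )
            return SegmentationResult(
                labels=LabelVolume(np.zeros(vol.shape, dtype=np.int32)),
                records=[],
                thresholds=est,
            )
    seg = _Segmenter(grid, est, cfg)
    lab, n = ndimage.label(grid.result.astype(bool), structure=_STRUCT_26)
    for comp in range(1, n + 1):
        seg.process(lab == comp, pass_no=1)

    block_labels = LabelVolume(seg.final)
    filtered = _morpho.filter_small_debris(block_labels, seg.crit_blocks.vol_min)
    kept = set(int(i) for i in np.unique(seg.final[filtered.labels > 0]))
    # keep records/provenance aligned with the surviving, renumbered labels
    survivors = [
        (rec, prov)
        for rec, prov in zip(seg.records, seg.provenance)
        if rec.id in kept
    ]
    records, provenance = [], []
    for new_id, (rec, prov) in enumerate(survivors, start=1):
        rec.id = new_id
        prov.label = new_id
        records.append(rec)
        provenance.append(prov)

    full = _refine.upsample_labels(
        filtered, scaled_shape=scaled.shape, full_shape=vol.shape, block=cfg.block
    )
    if cfg.refine:
        full = _refine.refine_surface(
            full, vol, _refine.RefinementParams(i_th=cfg.i_th)
        )
    return SegmentationResult(
        labels=full,
        records=records,
        thresholds=est,
        provenance=provenance,
        block_labels=filtered,
    )
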