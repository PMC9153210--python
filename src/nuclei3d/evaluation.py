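"""Detection and delineation accuracy against expert masks.

Matching follows the >50% coverage protocol: an expert nucleus is a true
positive when one algorithm label covers more than half of its area, and an
algorithm label that has claimed one expert nucleus is not re-checked against
others (those become under-segmentation false negatives). Every algorithm
label left unclaimed on the evaluated layer counts as a false positive —
whether it sits on empty background or is a superfluous fragment of a split
nucleus. Delineation accuracy is the Jaccard index averaged over the matched
pairs.

The matcher is dimension-agnostic, so the same code scores the paper-style
2D expert layer and full-3D synthetic ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .stack_io import GroundTruthLayer

Category = Literal["TP", "FN", "under-segmented"]

OVERLAY_COLOURS = {
    "TP": (0, 200, 0),
    "under-segmented": (230, 220, 0),
    "FN": (220, 0, 0),
    "FP": (40, 80, 255),
}


@dataclass
class MatchEntry:
    gt_id: int
    alg_id: int | None
    jaccard: float | None
    category: Category


@dataclass
class Matching:
    entries: list[MatchEntry]
    fp_labels: list[int]
    alg_count: int
    gt_count: int


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    ji_avg: float
    alg_count: int
    gt_count: int
    per_nucleus: list[MatchEntry] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "ji_avg": self.ji_avg,
            "alg_count": self.alg_count,
            "gt_count": self.gt_count,
        }


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """|A ∩ B| / |A ∪ B| of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def match_labels(alg: np.ndarray, gt: np.ndarray) -> Matching:
    """>50%-coverage matching between two integer label arrays (any ndim).

    Expert nuclei are processed in descending area; each algorithm label is
    claimable once as a TP.
    """
    alg = np.asarray(alg)
    gt = np.asarray(gt)
    if alg.shape != gt.shape:
        raise ValueError("label arrays must share the same shape")
    gt_ids, gt_areas = np.unique(gt[gt > 0], return_counts=True)
    alg_ids = np.unique(alg[alg > 0])
    order = np.argsort(-gt_areas, kind="stable")
    claimed: set[int] = set()
    entries: list[MatchEntry] = []
    for j in order:
        gid = int(gt_ids[j])
        gt_mask = gt == gid
        area = int(gt_areas[j])
        under = alg[gt_mask]
        cand_ids, cand_areas = np.unique(under[under > 0], return_counts=True)
        if len(cand_ids) == 0:
            entries.append(MatchEntry(gid, None, None, "FN"))
            continue
        best = int(np.argmax(cand_areas))
        best_id, overlap = int(cand_ids[best]), int(cand_areas[best])
        if overlap * 2 <= area:  # no label covers > 50%
            entries.append(MatchEntry(gid, None, None, "FN"))
            continue
        if best_id in claimed:
            entries.append(MatchEntry(gid, best_id, None, "under-segmented"))
            continue
        claimed.add(best_id)
        ji = jaccard(alg == best_id, gt_mask)
        entries.append(MatchEntry(gid, best_id, ji, "TP"))
    fp_labels = [int(i) for i in alg_ids if int(i) not in claimed]
    return Matching(
        entries=entries,
        fp_labels=fp_labels,
        alg_count=len(alg_ids),
        gt_count=len(gt_ids),
    )


def match_detections(alg_layer: np.ndarray, gt: GroundTruthLayer) -> Matching:
    """Match the algorithm's Z slice at the expert layer against the expert masks."""
    return match_labels(alg_layer, gt.mask)


def detection_metrics(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall (sensitivity) and F1 from raw counts (NaN when undefined)."""
    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    recall = tp / (tp + fn) if tp + fn > 0 else float("nan")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def compute_metrics(matching: Matching) -> EvaluationReport:
    """Counts, precision/recall/F1 and the average Jaccard over matched nuclei.

    With no matched nuclei the ratio metrics are reported as NaN markers, not
    as zero.
    """
    tp = sum(1 for e in matching.entries if e.category == "TP")
    fn = matching.gt_count - tp
    fp = matching.alg_count - tp
    precision, recall, f1 = detection_metrics(tp, fp, fn)
    jis = [e.jaccard for e in matching.entries if e.jaccard is not None]
    ji_avg = float(np.mean(jis)) if jis else float("nan")
    return EvaluationReport(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        ji_avg=ji_avg,
        alg_count=matching.alg_count,
        gt_count=matching.gt_count,
        per_nucleus=list(matching.entries),
    )


def render_overlay(
    alg_layer: np.ndarray, gt: GroundTruthLayer, matching: Matching
) -> np.ndarray:
    """RGB overlay: green TP, yellow under-segmented, red FN, blue FP labels."""
    h, w = gt.mask.shape
    img = np.zeros((h, w, 3), dtype=np.uint8)
    for fp_id in matching.fp_labels:
        img[alg_layer == fp_id] = OVERLAY_COLOURS["FP"]
    for entry in matching.entries:
        img[gt.mask == entry.gt_id] = OVERLAY_COLOURS[entry.category]
    return img
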