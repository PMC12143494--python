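"""Semantic segmentation evaluation.

Per-class confusion counts, ratio metrics (IoU, precision, recall,
F-score), the Mean False Distance (mean of the two directed Hausdorff
distances between predicted and ground-truth foreground voxel sets), and
the CREMI synaptic-cleft metrics (ADGT: average distance from predicted
foreground voxels to the nearest ground-truth voxel; ADF: the reverse;
CREMI score: their mean), plus aggregation over classes or independent
binary tasks.

Distances are computed on foreground voxel sets with the Euclidean
distance transform, optionally scaled by anisotropic voxel spacing.

Conventions for degenerate masks: if both foregrounds are empty, the ratio
metrics are 1.0 (perfect agreement); if exactly one is empty, ratio
metrics follow their formulas (0 where defined) and distance metrics are
reported as missing (``None``), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage


class EmptyMaskError(ValueError):
    """A distance metric was requested for an empty foreground mask."""


def _check_shapes(pred: np.ndarray, gt: np.ndarray) -> None:
    if pred.shape != gt.shape:
        raise ValueError(
            f"prediction shape {pred.shape} != ground truth shape {gt.shape}")


def confusion_counts(pred: np.ndarray, gt: np.ndarray,
                     class_id: int) -> Tuple[int, int, int, int]:
    """(tp, fp, fn, tn) over all voxels, treating ``class_id`` as foreground."""
    _check_shapes(pred, gt)
    p = pred == class_id
    g = gt == class_id
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return tp, fp, fn, tn


def semantic_scores(pred: np.ndarray, gt: np.ndarray,
                    class_id: int) -> Dict[str, float]:
    """IoU, precision, recall and F-score for one class.

    iou = tp/(tp+fp+fn); f = 2PR/(P+R).  Empty/empty returns all 1.0.
    """
    tp, fp, fn, _ = confusion_counts(pred, gt, class_id)
    if tp + fp + fn == 0:
        return {"iou": 1.0, "precision": 1.0, "recall": 1.0, "f_score": 1.0}
    iou = tp / (tp + fp + fn)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = (2 * precision * recall / (precision + recall)
         if precision + recall else 0.0)
    return {"iou": iou, "precision": precision, "recall": recall, "f_score": f}


def _distance_to(mask: np.ndarray,
                 spacing: Optional[Sequence[float]]) -> np.ndarray:
    """Euclidean distance from every voxel to the nearest True voxel."""
    return ndimage.distance_transform_edt(~mask, sampling=spacing)


def mean_false_distance(pred: np.ndarray, gt: np.ndarray,
                        spacing: Optional[Sequence[float]] = None) -> float:
    """Mean of the two directed Hausdorff distances between foreground sets.

    d(A->B) = max over a in A of the distance to the nearest b in B,
    Euclidean, scaled by ``spacing`` (one factor per axis).  Both masks
    must be non-empty.
    """
    _check_shapes(pred, gt)
    p = pred.astype(bool)
    g = gt.astype(bool)
    if not p.any() or not g.any():
        raise EmptyMaskError(
            "mean_false_distance undefined for an empty foreground mask")
    d_pred_to_gt = float(_distance_to(g, spacing)[p].max())
    d_gt_to_pred = float(_distance_to(p, spacing)[g].max())
    return 0.5 * (d_pred_to_gt + d_gt_to_pred)


def cremi_scores(pred: np.ndarray, gt: np.ndarray,
                 spacing: Optional[Sequence[float]] = None) -> Dict[str, Optional[float]]:
    """CREMI-style evaluation of a binary prediction.

    adgt: mean over predicted foreground voxels of the distance to the
    nearest ground-truth foreground voxel; adf: mean over ground-truth
    voxels of the distance to the nearest predicted voxel; cremi_score:
    (adgt + adf) / 2.  fp/fn counts and 1 - F-score come from the
    confusion table.  Distance terms are ``None`` when either mask is
    empty (not computable for a degenerate prediction).
    """
    _check_shapes(pred, gt)
    p = pred.astype(bool)
    g = gt.astype(bool)
    tp, fp, fn, _ = confusion_counts(p.astype(np.uint8), g.astype(np.uint8), 1)
    scores = semantic_scores(p.astype(np.uint8), g.astype(np.uint8), 1)
    block: Dict[str, Optional[float]] = {
        "fp": float(fp), "fn": float(fn),
        "one_minus_f": 1.0 - scores["f_score"],
    }
    if not p.any() or not g.any():
        block.update({"adgt": None, "adf": None, "cremi_score": None})
        return block
    adgt = float(_distance_to(g, spacing)[p].mean())
    adf = float(_distance_to(p, spacing)[g].mean())
    block.update({"adgt": adgt, "adf": adf,
                  "cremi_score": 0.5 * (adgt + adf)})
    return block


@dataclass
class MetricReport:
    """Per-class and aggregate segmentation metrics for one evaluation."""

    per_class: Dict[int, Dict[str, Optional[float]]]
    mean_iou: float
    mean_f: float
    cremi: Optional[Dict[str, Optional[float]]] = None

    def to_dict(self) -> dict:
        return {
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "mean_iou": self.mean_iou,
            "mean_f": self.mean_f,
            "cremi": self.cremi,
        }


def evaluate_segmentation(pred: np.ndarray, gt: np.ndarray,
                          n_classes: int,
                          spacing: Optional[Sequence[float]] = None,
                          include_background: bool = False,
                          with_cremi: bool = False) -> MetricReport:
    """Full per-class report with foreground-mean aggregates.

    ``n_classes`` counts classes including background (class 0); by default
    the aggregate means run over foreground classes only.  MFD is reported
    per class and never averaged with the ratio metrics; it is ``None``
    when either foreground is empty.
    """
    _check_shapes(pred, gt)
    first = 0 if include_background else 1
    per_class: Dict[int, Dict[str, Optional[float]]] = {}
    for cls in range(first, n_classes):
        scores: Dict[str, Optional[float]] = dict(semantic_scores(pred, gt, cls))
        try:
            scores["mfd"] = mean_false_distance(pred == cls, gt == cls, spacing)
        except EmptyMaskError:
            scores["mfd"] = None
        per_class[cls] = scores
    ious = [v["iou"] for v in per_class.values()]
    fs = [v["f_score"] for v in per_class.values()]
    cremi = None
    if with_cremi:
        cremi = cremi_scores(pred > 0, gt > 0, spacing)
    return MetricReport(per_class=per_class,
                        mean_iou=float(np.mean(ious)),
                        mean_f=float(np.mean(fs)),
                        cremi=cremi)


def aggregate(reports: Sequence[Dict[str, float]],
              scheme: str = "mean_over_tasks") -> Dict[str, float]:
    """Aggregate per-task or per-class metric dicts by unweighted mean.

    ``mean_over_tasks`` averages independent binary tasks (the convention
    for datasets whose structures are trained as separate binary
    segmentations); ``mean_over_classes`` averages foreground classes of a
    single multiclass task.  Both are plain unweighted means over the
    shared numeric keys.
    """
    if scheme not in ("mean_over_tasks", "mean_over_classes"):
        raise ValueError(f"unknown aggregation scheme {scheme!r}")
    if len(reports) == 0:
        raise ValueError("aggregate requires at least one report")
    keys = [k for k in reports[0]
            if all(isinstance(r.get(k), (int, float)) for r in reports)]
    return {k: float(np.mean([r[k] for r in reports])) for k in keys}
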