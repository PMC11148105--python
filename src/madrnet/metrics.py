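"""Confusion-count-based segmentation metrics.

All metrics derive from the per-image pixel confusion counts

    TP = |GT ∩ PR|,  TN = |~GT ∩ ~PR|,  FP = |~GT ∩ PR|,  FN = |GT ∩ ~PR|

between a binary ground-truth mask GT and a binary prediction PR:

    DSC       = 2TP / (2TP + FP + FN)
    IoU       = TP / (TP + FP + FN)        (DSC = 2 IoU / (1 + IoU))
    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)

Empty-mask convention: when both masks are empty, overlap metrics
(DSC/IoU/precision/recall) are 1 by convention (perfect agreement); when
exactly one is empty they are 0.  Soft predictions must be thresholded
before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "dsc",
    "iou",
    "accuracy",
    "precision",
    "recall",
    "all_metrics",
    "multiclass_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _check_binary(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be binary (threshold soft predictions first)")
    return a.astype(bool)


def confusion_counts(gt, pr) -> ConfusionCounts:
    """Pixel confusion tallies between two binary masks of equal shape."""
    gt = _check_binary(gt, "gt")
    pr = _check_binary(pr, "pr")
    if gt.shape != pr.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pr.shape}")
    tp = int(np.count_nonzero(gt & pr))
    tn = int(np.count_nonzero(~gt & ~pr))
    fp = int(np.count_nonzero(~gt & pr))
    fn = int(np.count_nonzero(gt & ~pr))
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num: int, den: int, empty_value: float = 1.0) -> float:
    return num / den if den else empty_value


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity coefficient; 1 when both masks are empty."""
    return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)


def iou(c: ConfusionCounts) -> float:
    """Jaccard index; 1 when both masks are empty."""
    return _ratio(c.tp, c.tp + c.fp + c.fn)


def accuracy(c: ConfusionCounts) -> float:
    return _ratio(c.tp + c.tn, c.total)


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn)


def all_metrics(c: ConfusionCounts) -> dict[str, float]:
    return {
        "dsc": dsc(c),
        "iou": iou(c),
        "accuracy": accuracy(c),
        "precision": precision(c),
        "recall": recall(c),
    }


def multiclass_report(gt, pr, num_classes: int,
                      include_background: bool = True,
                      average: str = "macro") -> dict:
    """One-vs-rest per-class metrics for integer label maps.

    Returns ``{"per_class": {label: {metric: value}}, "macro": {...}}``.
    ``include_background`` controls whether class 0 enters the macro mean;
    ``average='micro'`` pools confusion counts over classes instead.
    """
    gt = np.asarray(gt)
    pr = np.asarray(pr)
    if gt.shape != pr.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pr.shape}")
    for arr, name in ((gt, "gt"), (pr, "pr")):
        if arr.min() < 0 or arr.max() >= num_classes:
            raise ValueError(f"{name} labels out of range [0, {num_classes})")
    if average not in ("macro", "micro"):
        raise ValueError("average must be 'macro' or 'micro'")

    per_class: dict[int, dict[str, float]] = {}
    counts: dict[int, ConfusionCounts] = {}
    for m in range(num_classes):
        c = confusion_counts((gt == m).astype(np.uint8), (pr == m).astype(np.uint8))
        counts[m] = c
        per_class[m] = all_metrics(c)

    labels = [m for m in range(num_classes) if include_background or m != 0]
    if average == "macro":
        agg = {
            k: float(np.mean([per_class[m][k] for m in labels]))
            for k in ("dsc", "iou", "accuracy", "precision", "recall")
        }
    else:
        pooled = ConfusionCounts(
            tp=sum(counts[m].tp for m in labels),
            tn=sum(counts[m].tn for m in labels),
            fp=sum(counts[m].fp for m in labels),
            fn=sum(counts[m].fn for m in labels),
        )
        agg = all_metrics(pooled)
    return {"per_class": per_class, average: agg}
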