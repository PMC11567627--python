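"""Pixel-level evaluation: confusion counts and the four overlap metrics.

precision   = TP / (TP + FP)
sensitivity = TP / (TP + FN)         (recall)
IoU         = TP / (TP + FP + FN)    (Jaccard)
DSC         = 2 TP / (2 TP + FP + FN)  (Sorensen-Dice)

Degenerate denominators follow the convention: a metric whose denominator
is zero is 1 when the prediction is vacuously perfect (TP = FP = FN = 0,
e.g. empty prediction against empty truth) and 0 otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_counts",
           "segmentation_metrics", "evaluate_masks", "reports_to_frame"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    sensitivity: float
    iou: float
    dsc: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(d.pop("counts"))
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def confusion_counts(pred_mask: np.ndarray, gt_mask: np.ndarray) -> ConfusionCounts:
    """Tally TP/FP/FN/TN over two equally shaped binary masks."""
    pred = np.asarray(pred_mask)
    gt = np.asarray(gt_mask)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shape mismatch: {pred.shape} vs {gt.shape}")
    for name, m in (("prediction", pred), ("ground truth", gt)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask is not binary")
    pred = pred.astype(bool)
    gt = gt.astype(bool)
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: int, den: int, vacuous: bool) -> float:
    if den == 0:
        return 1.0 if vacuous else 0.0
    return num / den


def segmentation_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Compute the four overlap metrics from confusion counts."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    vacuous = tp == 0 and fp == 0 and fn == 0
    return MetricsReport(
        precision=_ratio(tp, tp + fp, vacuous),
        sensitivity=_ratio(tp, tp + fn, vacuous),
        iou=_ratio(tp, tp + fp + fn, vacuous),
        dsc=_ratio(2 * tp, 2 * tp + fp + fn, vacuous),
        counts=counts,
    )


def evaluate_masks(pred_mask: np.ndarray, gt_mask: np.ndarray) -> MetricsReport:
    return segmentation_metrics(confusion_counts(pred_mask, gt_mask))


def reports_to_frame(reports: dict[str, MetricsReport]) -> pd.DataFrame:
    """Per-sample metrics table (id, TP, FP, FN, TN, and the four metrics)."""
    rows = []
    for sample_id, rep in reports.items():
        c = rep.counts
        rows.append({"id": sample_id, "TP": c.tp, "FP": c.fp, "FN": c.fn,
                     "TN": c.tn, "precision": rep.precision,
                     "sensitivity": rep.sensitivity, "iou": rep.iou,
                     "dsc": rep.dsc})
    return pd.DataFrame(rows)
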