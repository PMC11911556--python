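"""Confusion-matrix metrics and ROC curves for binary site prediction.

Positive class = 1 = m5C site. Reported statistics:

    Sn  = TP / (TP + FN)                     (sensitivity / recall)
    Sp  = TN / (TN + FP)                     (specificity)
    Acc = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC is defined as 0 whenever a marginal in its denominator vanishes
(e.g. the classifier predicts a single class).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    acc: float
    sp: float
    sn: float
    mcc: float
    counts: ConfusionCounts
    auc: float | None = None

    def to_dict(self) -> dict:
        out = {
            "acc": self.acc,
            "sp": self.sp,
            "sn": self.sn,
            "mcc": self.mcc,
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
        }
        if self.auc is not None:
            out["auc"] = self.auc
        return out


@dataclass(frozen=True)
class ROCCurve:
    """Threshold-sweep ROC points (ties grouped) and trapezoid AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _as_binary(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return arr.astype(int)


def confusion(labels, predictions) -> ConfusionCounts:
    """Count TP/TN/FP/FN (positive = 1 = m5C site)."""
    y = _as_binary(labels, "labels")
    p = _as_binary(predictions, "predictions")
    if y.shape != p.shape:
        raise ValueError("labels and predictions differ in length")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def metrics(c: ConfusionCounts, auc: float | None = None) -> MetricsReport:
    """Acc/Sp/Sn/MCC from confusion counts.

    Sn (Sp) is 0 when there are no positives (negatives); MCC is 0
    when any marginal in its denominator is 0.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics of zero samples")
    pos, neg = c.tp + c.fn, c.tn + c.fp
    sn = c.tp / pos if pos else 0.0
    sp = c.tn / neg if neg else 0.0
    acc = (c.tp + c.tn) / c.total
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = (
        (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom else 0.0
    )
    return MetricsReport(acc=acc, sp=sp, sn=sn, mcc=mcc, counts=c, auc=auc)


def evaluate_predictions(
    labels, predictions, scores=None
) -> MetricsReport:
    """Full report from hard predictions, with AUC when scores given."""
    auc = None
    if scores is not None:
        labels_arr = _as_binary(labels, "labels")
        if len(set(labels_arr.tolist())) == 2:
            auc = roc(labels_arr, scores).auc
    return metrics(confusion(labels, predictions), auc=auc)


def roc(labels, scores) -> ROCCurve:
    """ROC curve by threshold sweep over unique scores; trapezoid AUC."""
    y = _as_binary(labels, "labels")
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores differ in length")
    if len(set(y.tolist())) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    return ROCCurve(fpr=fpr, tpr=tpr, auc=float(np.trapezoid(tpr, fpr)))
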