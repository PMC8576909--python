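"""Evaluation metrics: overlap scores, confusion-matrix ratios, ROC/AUC.

Segmentation quality is scored on hard masks with the Dice coefficient
2|T.P|/(|T|+|P|), precision |T.P|/|P| and recall |T.P|/|T|.
Classification is scored from TP/FP/TN/FN counts (accuracy, recall a.k.a.
sensitivity, specificity) and by the ROC curve with trapezoidal AUC,
which equals the probability that a random malignant case outranks a
random benign one (ties half credit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _as_binary(M):
    v = np.asarray(getattr(M, "values", M))
    return v.astype(bool)


def dice_coefficient(P, T) -> float:
    P, T = _as_binary(P), _as_binary(T)
    if P.shape != T.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {T.shape}")
    ps, ts = int(P.sum()), int(T.sum())
    if ps + ts == 0:
        raise ValueError("Dice undefined: both masks empty")
    return 2.0 * float(np.logical_and(P, T).sum()) / (ps + ts)


def precision(P, T) -> float:
    """|T.P| / |P|; NaN (missing) when nothing is predicted."""
    P, T = _as_binary(P), _as_binary(T)
    ps = int(P.sum())
    if ps == 0:
        return float("nan")
    return float(np.logical_and(P, T).sum()) / ps


def recall(P, T) -> float:
    """|T.P| / |T|; NaN (missing) when the reference is empty."""
    P, T = _as_binary(P), _as_binary(T)
    ts = int(T.sum())
    if ts == 0:
        return float("nan")
    return float(np.logical_and(P, T).sum()) / ts


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.total < 1:
            raise ValueError("confusion matrix must count at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        """Labels are 1 = positive (malignant), 0 = negative (benign)."""
        y_true = np.asarray(y_true).astype(bool)
        y_pred = np.asarray(y_pred).astype(bool)
        if y_true.shape != y_pred.shape:
            raise ValueError("label arrays differ in shape")
        return cls(
            tp=int(np.sum(y_true & y_pred)),
            fp=int(np.sum(~y_true & y_pred)),
            tn=int(np.sum(~y_true & ~y_pred)),
            fn=int(np.sum(y_true & ~y_pred)),
        )


def classification_metrics(cm: ConfusionMatrix):
    """(accuracy, recall, specificity); class-free denominators give NaN."""
    acc = (cm.tp + cm.tn) / cm.total
    rec = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else float("nan")
    spec = cm.tn / (cm.fp + cm.tn) if (cm.fp + cm.tn) > 0 else float("nan")
    return acc, rec, spec


def roc_curve(scores, labels):
    """ROC points by threshold sweep over the unique scores.

    Returns (fpr, tpr) arrays from (0,0) to (1,1), one step per distinct
    score value (tied scores move diagonally, which gives ties half
    credit under the trapezoid rule).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # cumulative counts at each distinct-score boundary
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.r_[distinct, s.size - 1]
    tp = np.cumsum(y)[idx]
    fp = np.cumsum(1 - y)[idx]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    return fpr, tpr


def roc_auc(scores, labels):
    """(fpr, tpr, auc) with trapezoidal AUC == pairwise rank statistic."""
    fpr, tpr = roc_curve(scores, labels)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc
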