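"""Binary-classification metrics for link prediction.

Threshold metrics (accuracy, precision, recall, F1) come from the confusion
counts at a 0.5 cutoff; ranking metrics are AUC (tie-aware Mann-Whitney
probability that a random positive outranks a random negative) and AUPR
(step-wise average precision, no linear interpolation — the convention that
penalizes false positives hardest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "ConfusionCounts",
    "classification_metrics",
    "roc_auc",
    "pr_auc",
    "f1_score_from_pr",
    "METRIC_NAMES",
]

METRIC_NAMES = ("auc", "aupr", "accuracy", "precision", "recall", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def f1_score_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _check_inputs(scores, labels):
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=int).ravel()
    if s.size != y.size:
        raise ValueError(f"{s.size} scores vs {y.size} labels")
    if s.size == 0:
        raise ValueError("need at least one scored pair")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return s, y


def classification_metrics(scores, labels, threshold: float = 0.5):
    """Confusion counts and threshold metrics at the given score cutoff.

    Ratios with a zero denominator are reported as 0.0 with a warning.
    """
    s, y = _check_inputs(scores, labels)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    counts = ConfusionCounts(tp, tn, fp, fn)

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting 0.0",
                          RuntimeWarning, stacklevel=3)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    report = {
        "accuracy": (tp + tn) / counts.total,
        "precision": precision,
        "recall": recall,
        "f1": f1_score_from_pr(precision, recall),
    }
    return counts, report


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; exact and tie-aware (ties count 1/2)."""
    s, y = _check_inputs(scores, labels)
    if y.min() == y.max():
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y, s))


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall curve as step-wise average precision."""
    s, y = _check_inputs(scores, labels)
    if y.sum() == 0:
        raise ValueError("AUPR requires at least one positive")
    return float(average_precision_score(y, s))
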