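"""Classification and regression metrics used across the pipeline.

Classification metrics are computed from raw confusion counts; regression
metrics from paired actual/predicted vectors.  All ratio metrics return
fractions (accuracy 0.93, not 93%); presentation scaling is left to callers.

Conventions for degenerate denominators:

* ``mcc`` returns 0 when any marginal of the confusion matrix is empty (the
  standard convention for an uninformative classifier);
* each SMAPE term with both actual and predicted equal to zero contributes 0
  (its limit value);
* every other zero denominator raises :class:`~cardiokit.exceptions.MetricError`
  naming the metric.

``mpe`` follows the definition used throughout this pipeline's evaluation
protocol: the mean of |predicted - actual| / actual, i.e. an absolute
percentage error, despite the "percentage error" name suggesting a signed
quantity elsewhere in the literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import MetricError, ShapeError

__all__ = [
    "ConfusionCounts",
    "confusion_from_labels",
    "accuracy",
    "precision",
    "f1",
    "mcc",
    "csi",
    "fpr",
    "rmse",
    "smape",
    "mae",
    "mpe",
    "classification_report",
    "regression_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP / TN / FP / FN tallies of a binary classifier."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise MetricError(f"confusion count {name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_from_labels(y_true, y_pred) -> ConfusionCounts:
    """Tally a :class:`ConfusionCounts` from 0/1 label vectors."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ShapeError("label vectors must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _require(condition: bool, metric: str) -> None:
    if not condition:
        raise MetricError(f"{metric}: zero denominator")


def accuracy(c: ConfusionCounts) -> float:
    _require(c.total > 0, "accuracy")
    return (c.tp + c.tn) / c.total


def precision(c: ConfusionCounts) -> float:
    _require(c.tp + c.fp > 0, "precision")
    return c.tp / (c.tp + c.fp)


def f1(c: ConfusionCounts) -> float:
    _require(2 * c.tp + c.fp + c.fn > 0, "f1")
    return 2 * c.tp / (2 * c.tp + c.fp + c.fn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 on empty marginals."""
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def csi(c: ConfusionCounts) -> float:
    """Critical success index TP / (TP + FP + FN)."""
    _require(c.tp + c.fp + c.fn > 0, "csi")
    return c.tp / (c.tp + c.fp + c.fn)


def fpr(c: ConfusionCounts) -> float:
    """False positive rate FP / (FP + TN)."""
    _require(c.fp + c.tn > 0, "fpr")
    return c.fp / (c.fp + c.tn)


def _paired(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape or actual.ndim != 1:
        raise ShapeError("actual and predicted must be 1-D vectors of equal length")
    if actual.size == 0:
        raise MetricError("regression metrics need at least one data point")
    return actual, predicted


def rmse(actual, predicted) -> float:
    actual, predicted = _paired(actual, predicted)
    return float(np.sqrt(np.mean((actual - predicted) ** 2)))


def mae(actual, predicted) -> float:
    actual, predicted = _paired(actual, predicted)
    return float(np.mean(np.abs(actual - predicted)))


def smape(actual, predicted) -> float:
    """Symmetric mean absolute percentage error (fraction; bounded by 2)."""
    actual, predicted = _paired(actual, predicted)
    denom = (np.abs(actual) + np.abs(predicted)) / 2.0
    terms = np.zeros_like(actual)
    nonzero = denom > 0
    terms[nonzero] = np.abs(predicted[nonzero] - actual[nonzero]) / denom[nonzero]
    return float(np.mean(terms))


def mpe(actual, predicted) -> float:
    """Mean of |predicted - actual| / actual; every actual must be nonzero."""
    actual, predicted = _paired(actual, predicted)
    _require(bool(np.all(actual != 0)), "mpe")
    return float(np.mean(np.abs(predicted - actual) / actual))


def classification_report(c: ConfusionCounts, percent: bool = False) -> dict[str, float]:
    """All six classification metrics as a dict; optionally scaled to percent
    (mcc excluded from percent scaling since it lives in [-1, 1])."""
    scale = 100.0 if percent else 1.0
    return {
        "accuracy": accuracy(c) * scale,
        "precision": precision(c) * scale,
        "f1": f1(c) * scale,
        "mcc": mcc(c),
        "csi": csi(c) * scale,
        "fpr": fpr(c) * scale,
    }


def regression_report(actual, predicted, percent: bool = False) -> dict[str, float]:
    scale = 100.0 if percent else 1.0
    return {
        "rmse": rmse(actual, predicted),
        "mae": mae(actual, predicted),
        "smape": smape(actual, predicted) * scale,
        "mpe": mpe(actual, predicted) * scale,
    }
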