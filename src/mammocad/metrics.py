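"""Evaluation metrics for imagewise benign/malignant classification.

The positive class is malignant (label 1). Alongside the standard rates —
sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
(TP+TN)/(TP+TN+FP+FN), precision, F1 — the report includes the
false-positives-per-image rate FPi = FP/N with N the number of evaluated
images, and the trapezoidal area under the ROC curve. Recall shares the
sensitivity formula and is reported as the same number. Metrics with a zero
denominator raise :class:`UndefinedMetricError` rather than silently
returning 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

__all__ = [
    "UndefinedMetricError",
    "ConfusionCounts",
    "MetricsReport",
    "confusion_from_predictions",
    "sensitivity",
    "specificity",
    "precision",
    "accuracy",
    "f1_score",
    "fpi",
    "roc_curve_points",
    "auc",
    "full_report",
]


class UndefinedMetricError(ZeroDivisionError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies plus the number of evaluated images N."""

    tp: int
    tn: int
    fp: int
    fn: int
    n_images: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_images < 1:
            raise ValueError("n_images must be at least 1")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """One row of an evaluation table; ``auc`` is NaN when undefined."""

    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    precision: float
    recall: float
    fpi: float
    auc: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            "fpi": self.fpi,
            "auc": self.auc,
        }


def confusion_from_predictions(
    y_true: Sequence[int], y_pred: Sequence[int], n_images: Optional[int] = None
) -> ConfusionCounts:
    """Tally a binary confusion with malignant (1) as the positive class."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if not (np.isin(yt, (0, 1)).all() and np.isin(yp, (0, 1)).all()):
        raise ValueError("labels must be 0 or 1")
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
        n_images=n_images if n_images is not None else len(yt),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        raise UndefinedMetricError(f"{name} is undefined (zero denominator)")
    return num / den


def sensitivity(c: ConfusionCounts) -> float:
    """True-positive rate TP / (TP + FN)."""
    return _ratio(c.tp, c.tp + c.fn, "sensitivity")


def specificity(c: ConfusionCounts) -> float:
    """True-negative rate TN / (TN + FP)."""
    return _ratio(c.tn, c.tn + c.fp, "specificity")


def precision(c: ConfusionCounts) -> float:
    """Positive predictive value TP / (TP + FP)."""
    return _ratio(c.tp, c.tp + c.fp, "precision")


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    return _ratio(c.tp + c.tn, c.total, "accuracy")


def f1_score(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and sensitivity."""
    p = precision(c)
    r = sensitivity(c)
    if p + r == 0:
        raise UndefinedMetricError("f1 is undefined (precision + recall = 0)")
    return 2 * p * r / (p + r)


def fpi(c: ConfusionCounts) -> float:
    """False positives per evaluated image, FP / N."""
    return c.fp / c.n_images


def roc_curve_points(y_true: Sequence[int], scores: Sequence[float]):
    """ROC points (fpr, tpr) from sweeping the threshold over unique scores.

    Tied scores collapse into a single ROC step, which gives tied pairs
    half credit in the resulting area (the Mann-Whitney convention).
    """
    yt = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    n_pos = int((yt == 1).sum())
    n_neg = int((yt == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC is undefined for single-class labels")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = yt[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep only the last index of each tied-score run
    last_of_run = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tps[last_of_run] / n_pos]
    fpr = np.r_[0.0, fps[last_of_run] / n_neg]
    return fpr, tpr


def auc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Trapezoidal area under the ROC curve."""
    fpr, tpr = roc_curve_points(y_true, scores)
    return float(np.trapezoid(tpr, fpr))


def full_report(
    y_true: Sequence[int],
    scores: Sequence[float],
    threshold: float = 0.5,
    n_images: Optional[int] = None,
) -> MetricsReport:
    """Threshold the malignancy scores and compute every report column.

    ``scores`` are class-1 (malignant) probabilities in [0, 1]; a score at
    or above ``threshold`` predicts malignant. With single-class labels the
    AUC column is NaN and the defined metrics are still reported.
    """
    s = np.asarray(scores, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must be probabilities in [0, 1]")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    yp = (s >= threshold).astype(int)
    c = confusion_from_predictions(y_true, yp, n_images=n_images)

    def _or_nan(fn):
        try:
            return fn(c)
        except UndefinedMetricError:
            return float("nan")

    try:
        area = auc(y_true, s)
    except UndefinedMetricError:
        area = float("nan")
    sens = _or_nan(sensitivity)
    return MetricsReport(
        sensitivity=sens,
        specificity=_or_nan(specificity),
        accuracy=_or_nan(accuracy),
        f1=_or_nan(f1_score),
        precision=_or_nan(precision),
        recall=sens,
        fpi=fpi(c),
        auc=area,
    )
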