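"""Classification metrics, the 0.5 normal-probability decision rule, and
fold summaries with 95% t-based confidence intervals.

The positive class is aspiration throughout. A sample is called normal only
when its normal-class probability strictly exceeds the threshold
(P(normal) > 0.5), the conservative rule adopted because aspiration misses
are the costly error; otherwise it is called aspiration.

Percentage-valued metrics (accuracy, sensitivity, specificity, PPV, NPV)
are reported on the 0-100 scale; AUC, F1 and losses on the unit scale.
Confidence intervals are mean +/- t(0.975, n-1) * sd / sqrt(n) over folds
and are deliberately not clipped to [0, 100].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

NORMAL, ASPIRATION = 0, 1


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts with aspiration as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Per-fold metrics; percentage fields on the 0-100 scale."""

    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    ppv: float
    npv: float
    loss: float = math.nan
    train_accuracy: float = math.nan
    train_loss: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def classify(prob_aspiration: float, threshold: float = 0.5) -> int:
    """Normal iff P(normal) = 1 - P(aspiration) strictly exceeds threshold."""
    if not (0.0 <= prob_aspiration <= 1.0):
        raise ValueError("probability must lie in [0, 1]")
    return NORMAL if (1.0 - prob_aspiration) > threshold else ASPIRATION


def confusion_counts(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: int, den: int) -> float:
    """A metric with a zero denominator is undefined (NaN), never 0."""
    return num / den if den > 0 else math.nan


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity/specificity/PPV/NPV/accuracy as percentages; F1 on [0, 1]."""
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    ppv = _ratio(c.tp, c.tp + c.fp)
    npv = _ratio(c.tn, c.tn + c.fn)
    acc = _ratio(c.tp + c.tn, c.total)
    if math.isnan(ppv) or math.isnan(sens) or (ppv + sens) == 0:
        f1 = math.nan
    else:
        f1 = 2.0 * ppv * sens / (ppv + sens)
    return {
        "accuracy": 100.0 * acc,
        "sensitivity": 100.0 * sens,
        "specificity": 100.0 * spec,
        "ppv": 100.0 * ppv,
        "npv": 100.0 * npv,
        "f1": f1,
    }


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Probability a random aspiration score exceeds a random normal score,
    ties counted 1/2 (rank/midrank formulation)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def roc_points(labels: Sequence[int], scores: Sequence[float]):
    """ROC curve points (fpr, tpr, threshold) for plotting, one row each."""
    from sklearn.metrics import roc_curve

    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thresholds = roc_curve(labels, np.asarray(scores, dtype=np.float64))
    return [
        {"fpr": float(f), "tpr": float(t), "threshold": float(th)}
        for f, t, th in zip(fpr, tpr, thresholds)
    ]


def bce_loss(probs: Sequence[float], labels: Sequence[int], eps: float = 1e-12) -> float:
    """Mean binary cross-entropy of aspiration-class probabilities."""
    p = np.clip(np.asarray(probs, dtype=np.float64), eps, 1.0 - eps)
    y = np.asarray(labels, dtype=np.float64)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())


def compute_report(
    labels: Sequence[int],
    probs_aspiration: Sequence[float],
    threshold: float = 0.5,
    train_accuracy: float = math.nan,
    train_loss: float = math.nan,
) -> MetricsReport:
    """Score one fold's test split from aspiration probabilities."""
    preds = [classify(p, threshold) for p in probs_aspiration]
    cm = confusion_metrics(confusion_counts(labels, preds))
    return MetricsReport(
        auc=roc_auc(labels, probs_aspiration),
        loss=bce_loss(probs_aspiration, labels),
        train_accuracy=train_accuracy,
        train_loss=train_loss,
        **cm,
    )


@dataclass
class MetricSummary:
    mean: float
    ci_low: float
    ci_high: float
    max: float


def summarize_folds(reports: Sequence[MetricsReport]) -> dict[str, MetricSummary]:
    """Per-metric mean, 95% t-interval over folds, and max.

    Intervals are not clipped; NaN fold values are excluded per metric.
    """
    if len(reports) < 2:
        raise ValueError("need >= 2 fold reports for a confidence interval")
    summary: dict[str, MetricSummary] = {}
    for f in fields(MetricsReport):
        vals = np.array([getattr(r, f.name) for r in reports], dtype=np.float64)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            summary[f.name] = MetricSummary(math.nan, math.nan, math.nan, math.nan)
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        half = float(stats.t.ppf(0.975, vals.size - 1)) * sd / math.sqrt(vals.size)
        summary[f.name] = MetricSummary(mean, mean - half, mean + half, float(vals.max()))
    return summary
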