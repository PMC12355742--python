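"""Evaluation metrics for imbalanced binary outcome prediction.

AUPRC is the primary comparison metric: with rare poor outcomes the
precision-recall curve is far more sensitive to ranking quality among the
positive class than the ROC curve.  AUPRC is computed as step-wise average
precision (the mean of precision at each recall increment, no trapezoidal
interpolation), AUC as the trapezoidal ROC area, which equals the
Mann-Whitney probability of correct ranking with ties counted half.
Thresholded metrics (recall, specificity, F1) use a configurable operating
point, 0.5 by default.  Fold aggregation reports mean and sample (ddof=1)
standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

THRESHOLDED = ("recall", "specificity", "f1")
METRIC_NAMES = ("auc", "auprc") + THRESHOLDED


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given label composition."""


class AggregationError(ValueError):
    """Raised when fold reports cannot be aggregated."""


def _check(scores, labels):
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return scores, labels


def auc(scores, labels) -> float:
    """Area under the ROC curve; requires both classes to be present."""
    scores, labels = _check(scores, labels)
    if labels.min() == labels.max():
        raise UndefinedMetricError("AUC undefined with a single class")
    return float(roc_auc_score(labels, scores))


def auprc(scores, labels) -> float:
    """Step-wise average precision; requires at least one positive."""
    scores, labels = _check(scores, labels)
    if labels.sum() == 0:
        raise UndefinedMetricError("AUPRC undefined without positives")
    return float(average_precision_score(labels, scores))


def thresholded_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """Recall, specificity and F1 at a fixed probability threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    scores, labels = _check(scores, labels)
    pred = (scores > threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return {"recall": recall, "specificity": specificity, "f1": f1}


def evaluate(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """All five reported metrics for one fold."""
    out = {"auc": auc(scores, labels), "auprc": auprc(scores, labels)}
    out.update(thresholded_metrics(scores, labels, threshold))
    return out


@dataclass
class MetricReport:
    """Per-fold metric values with mean/SD aggregation for one experiment arm."""

    per_fold: dict[str, list[float]]
    mean: dict[str, float]
    sd: dict[str, float]
    threshold: float = 0.5
    n_pos: int = 0
    n_neg: int = 0
    label: str = ""
    extras: dict = field(default_factory=dict)

    @property
    def prevalence(self) -> float:
        total = self.n_pos + self.n_neg
        return self.n_pos / total if total else float("nan")

    def row(self) -> dict[str, str]:
        """One results-table row, formatted 'mean (SD)' per metric."""
        return {m: f"{self.mean[m]:.3f} ({self.sd[m]:.3f})" for m in METRIC_NAMES}


def aggregate(fold_metrics: list[dict[str, float]], threshold: float = 0.5,
              n_pos: int = 0, n_neg: int = 0, label: str = "") -> MetricReport:
    """Aggregate per-fold metric dicts into mean and sample SD.

    A single fold is rejected: a standard deviation over one value is
    meaningless and would silently hide a broken suite.
    """
    if len(fold_metrics) < 2:
        raise AggregationError("aggregation requires at least two folds")
    keys = set(fold_metrics[0])
    if any(set(fm) != keys for fm in fold_metrics):
        raise AggregationError("fold reports carry different metric sets")
    per_fold = {m: [float(fm[m]) for fm in fold_metrics] for m in keys}
    mean = {m: float(np.mean(v)) for m, v in per_fold.items()}
    sd = {m: float(np.std(v, ddof=1)) for m, v in per_fold.items()}
    return MetricReport(per_fold=per_fold, mean=mean, sd=sd,
                        threshold=threshold, n_pos=n_pos, n_neg=n_neg,
                        label=label)
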