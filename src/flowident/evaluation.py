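"""Performance metrics for single-cell classification and gradient recovery.

* accuracy — fraction of correctly labeled cells, 1/N * sum 1(y_hat == y).
  A macro tp/tn form (per-class (tp_j + tn_j)/N averaged over classes) is
  provided as a cross-check; the two coincide for two classes, while for
  S > 2 the macro form counts true negatives and systematically exceeds the
  fraction correct, so the fraction-correct form is the headline metric.
* auc_binary — area under the ROC curve via the Mann-Whitney rank statistic
  (ties credited 1/2): the probability that a random positive outranks a
  random negative, insensitive to class imbalance.
* rmse_gradient — root mean squared error between target and predicted
  abundances across the levels of a gradient.
* confusion_matrix — row-normalized S x S matrix; entry (i, j) is the
  fraction of population i predicted as population j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "ConfusionMatrix",
    "GradientReport",
    "MetricsReport",
    "accuracy",
    "accuracy_macro_tptn",
    "auc_binary",
    "confusion_matrix",
    "evaluate_split",
    "rmse_gradient",
]


def _as_labels(y_true, y_pred):
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("need at least one label")
    return y_true, y_pred


def accuracy(y_true, y_pred) -> float:
    """Fraction of correct single-cell predictions."""
    y_true, y_pred = _as_labels(y_true, y_pred)
    return float(np.mean(y_true == y_pred))


def accuracy_macro_tptn(y_true, y_pred) -> float:
    """Macro-averaged (tp_j + tn_j) / N over classes; binary == accuracy."""
    y_true, y_pred = _as_labels(y_true, y_pred)
    classes = np.unique(np.concatenate([y_true, y_pred]))
    n = y_true.size
    per_class = []
    for cls in classes:
        tp = np.sum((y_true == cls) & (y_pred == cls))
        tn = np.sum((y_true != cls) & (y_pred != cls))
        per_class.append((tp + tn) / n)
    return float(np.mean(per_class))


def auc_binary(y_true, scores, positive=None) -> float:
    """AUC from the Mann-Whitney U statistic, ties counted 1/2.

    ``scores`` are positive-class scores; ``positive`` defaults to the
    lexicographically larger of the two labels.
    """
    y_true = np.asarray(y_true).astype(str)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if scores.size and not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    classes = np.unique(y_true)
    if classes.size != 2:
        raise ValueError(f"AUC needs exactly 2 classes present, got {classes.size}")
    if positive is None:
        positive = classes[1]
    pos = y_true == str(positive)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)  # midranks give the 1/2 tie credit
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def rmse_gradient(p_target, p_pred) -> float:
    """sqrt(mean((p_i - p_hat_i)^2)) over the levels of a gradient."""
    p_target = np.asarray(p_target, dtype=float)
    p_pred = np.asarray(p_pred, dtype=float)
    if p_target.shape != p_pred.shape or p_target.size == 0:
        raise ValueError("target and predicted vectors must have equal length >= 1")
    return float(np.sqrt(np.mean((p_target - p_pred) ** 2)))


@dataclass
class ConfusionMatrix:
    classes: list
    counts: np.ndarray      # raw counts, true rows x predicted columns
    fractions: np.ndarray   # row-normalized; all-zero rows flagged below
    zero_support: np.ndarray

    def trace_accuracy(self) -> float:
        """Fraction correct recomputed from the raw counts (exact identity)."""
        return float(np.trace(self.counts) / self.counts.sum())


def confusion_matrix(y_true, y_pred, classes) -> ConfusionMatrix:
    y_true, y_pred = _as_labels(y_true, y_pred)
    classes = [str(c) for c in classes]
    known = set(classes)
    unknown = sorted(set(y_true).union(y_pred) - known)
    if unknown:
        raise ValueError(f"labels outside the declared classes: {unknown}")
    counts = _sk_confusion(y_true, y_pred, labels=classes)
    support = counts.sum(axis=1)
    zero = support == 0
    with np.errstate(invalid="ignore"):
        fractions = counts / np.where(zero, 1, support)[:, None]
    fractions[zero] = 0.0
    return ConfusionMatrix(
        classes=classes,
        counts=counts,
        fractions=fractions,
        zero_support=zero,
    )


@dataclass
class MetricsReport:
    """Held-out performance of one classifier on one community."""

    accuracy: float
    auc: float | None
    confusion: ConfusionMatrix
    n_test: int


@dataclass
class GradientReport:
    """Predicted vs target first-population abundances along a gradient."""

    levels: np.ndarray
    p_hat1: np.ndarray
    rmse: float


def evaluate_split(model, test_events, test_labels) -> MetricsReport:
    """Accuracy, confusion matrix and (binary only) AUC on a held-out set.

    The AUC positive class is the second entry of ``model.classes``; the
    statistic is symmetric (AUC_pos + AUC_neg = 1 pointwise in ranking
    quality), so the choice only fixes an orientation.
    """
    from .classify import predict_labels, predict_scores

    y_pred = predict_labels(model, test_events)
    acc = accuracy(test_labels, y_pred)
    cm = confusion_matrix(test_labels, y_pred, model.classes)
    auc = None
    if model.classes.size == 2:
        scores = predict_scores(model, test_events)[:, 1]
        auc = auc_binary(test_labels, scores, positive=model.classes[1])
    return MetricsReport(
        accuracy=acc, auc=auc, confusion=cm, n_test=len(test_labels)
    )
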