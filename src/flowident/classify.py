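"""Single-cell classifiers and the plug-in composition estimator.

Two off-the-shelf classifiers are wrapped behind one surface:

* LDA — linear discriminant analysis, class-conditional Gaussians with a
  shared covariance. No hyperparameters; a tiny ridge (1e-6 of the average
  covariance eigenvalue, via the eigen solver's shrinkage) keeps the pooled
  covariance invertible on near-degenerate channels.
* RF — random forest of 200 unpruned trees grown on bootstrap samples,
  gini splits, floor(sqrt(K)) features per split for K channels (3 for the
  12-parameter panel).

Features are used raw (no standardization). Community composition is
estimated by the plug-in count estimator: the fraction of cells assigned to
each taxon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier

from .fcs_io import EventMatrix

__all__ = [
    "ClassifierSpec",
    "CompositionEstimate",
    "FittedClassifier",
    "estimate_composition",
    "fit",
    "predict_labels",
    "predict_scores",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Configuration of a single-cell classifier.

    ``rf_features_per_split=None`` means floor(sqrt(K)) where K is the
    number of training channels. LDA ignores the ``rf_*`` fields.
    """

    method: str = "RF"
    rf_n_trees: int = 200
    rf_split_criterion: str = "gini"
    rf_features_per_split: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("LDA", "RF"):
            raise ValueError(f"method must be 'LDA' or 'RF', got {self.method!r}")
        if self.rf_n_trees < 1:
            raise ValueError("rf_n_trees must be >= 1")
        if self.rf_split_criterion != "gini":
            raise ValueError("only the gini split criterion is supported")


@dataclass
class FittedClassifier:
    spec: ClassifierSpec
    classes: np.ndarray          # lexicographically ordered taxon ids
    channels: list               # training channel order
    sk_model: object = field(repr=False, default=None)


@dataclass
class CompositionEstimate:
    """Predicted per-taxon cell counts and relative abundances."""

    taxa: list
    counts: np.ndarray
    p_hat: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.p_hat = np.asarray(self.p_hat, dtype=float)
        if abs(self.p_hat.sum() - 1.0) > 1e-9:
            raise ValueError("estimated composition must sum to 1")


def fit(spec: ClassifierSpec, train_events: EventMatrix, train_labels) -> FittedClassifier:
    """Train a classifier on a labeled community.

    Requires at least two distinct labels and finite features. RF training is
    seeded through ``spec.seed`` and fully reproducible.
    """
    labels = np.asarray(train_labels)
    if labels.shape[0] != train_events.n_events:
        raise ValueError("one label per training event required")
    classes = np.unique(labels.astype(str))
    if classes.size < 2:
        raise ValueError("training set must contain at least 2 distinct labels")
    X = train_events.values
    if X.size and not np.all(np.isfinite(X)):
        raise ValueError("training features must be finite")

    if spec.method == "LDA":
        model = LinearDiscriminantAnalysis(solver="eigen", shrinkage=1e-6)
    else:
        k = spec.rf_features_per_split
        if k is None:
            k = max(1, math.floor(math.sqrt(train_events.n_channels)))
        if not (1 <= k <= train_events.n_channels):
            raise ValueError("rf_features_per_split must lie in [1, K]")
        model = RandomForestClassifier(
            n_estimators=spec.rf_n_trees,
            criterion=spec.rf_split_criterion,
            max_features=k,
            bootstrap=True,
            random_state=int(spec.seed),
        )
    model.fit(X, labels.astype(str))
    return FittedClassifier(
        spec=spec,
        classes=np.asarray(model.classes_, dtype=object),
        channels=list(train_events.channels),
        sk_model=model,
    )


def _aligned_values(model: FittedClassifier, events: EventMatrix) -> np.ndarray:
    missing = [ch for ch in model.channels if ch not in events.channels]
    if missing:
        raise ValueError(f"events lack training channels: {missing}")
    idx = [events.index(ch) for ch in model.channels]
    return events.values[:, idx]


def predict_scores(model: FittedClassifier, events: EventMatrix) -> np.ndarray:
    """Per-event per-class membership scores.

    LDA scores are posterior probabilities (Bayes' theorem under the shared
    Gaussian model); RF scores are the fraction of trees voting for each
    class. Rows sum to 1; column order follows ``model.classes``.
    """
    X = _aligned_values(model, events)
    if X.shape[0] == 0:
        return np.zeros((0, model.classes.size))
    scores = model.sk_model.predict_proba(X)
    return scores


def predict_labels(model: FittedClassifier, events: EventMatrix) -> np.ndarray:
    """One taxon label per event: the argmax of the class scores.

    Ties break toward the first class in ``model.classes`` (lexicographic
    taxon order), keeping predictions deterministic.
    """
    scores = predict_scores(model, events)
    if scores.shape[0] == 0:
        return np.array([], dtype=object)
    return model.classes[np.argmax(scores, axis=1)]


def estimate_composition(model: FittedClassifier, events: EventMatrix) -> CompositionEstimate:
    """Plug-in composition: fraction of cells assigned to each taxon."""
    if events.n_events == 0:
        raise ValueError("cannot estimate a composition from zero events")
    predicted = predict_labels(model, events)
    counts = np.array(
        [int(np.sum(predicted == taxon)) for taxon in model.classes], dtype=int
    )
    return CompositionEstimate(
        taxa=list(model.classes),
        counts=counts,
        p_hat=counts / counts.sum(),
    )
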