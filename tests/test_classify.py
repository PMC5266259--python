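"""Single-cell classifiers: contracts, scores and composition estimation."""

import numpy as np
import pytest

from flowident import (
    CANONICAL_PANEL,
    ClassifierSpec,
    EventMatrix,
    build_even_community,
    confusion_matrix,
    estimate_composition,
    evaluate_split,
    fit,
    make_population_model,
    predict_labels,
    predict_scores,
    simulate_population,
    split_train_test,
)
from flowident.synthetic import _BASE_H_MEANS, DriftModel


def _labeled_pair(separation: float, n: int = 1500, seed: int = 0):
    """Two populations `separation` units apart on FL1/FL3, as arcsinh features.

    Classifier unit tests operate in the transformed space where the clusters
    are Gaussian, isolating the classifier contract from the heavy-tailed raw
    scale (which the pipeline-level tests cover).
    """
    shift = np.array([separation / 2, 0, separation / 2, 0, 0, 0])
    no_drift = DriftModel(0.0, 0.0)
    a = simulate_population(
        make_population_model("a", _BASE_H_MEANS + shift, n), no_drift, seed=seed
    )
    b = simulate_population(
        make_population_model("b", _BASE_H_MEANS - shift, n), no_drift, seed=seed + 1
    )
    events = EventMatrix(
        list(CANONICAL_PANEL), np.arcsinh(np.vstack([a.values, b.values]))
    )
    labels = np.array(["a"] * n + ["b"] * n, dtype=object)
    return events, labels


def _split(events, labels, seed=0):
    rng = np.random.default_rng(seed)
    idx = rng.permutation(events.n_events)
    cut = int(0.7 * len(idx))
    tr, te = idx[:cut], idx[cut:]
    return events.take(tr), labels[tr], events.take(te), labels[te]


@pytest.mark.parametrize("method", ["LDA", "RF"])
class TestSeparability:
    def test_well_separated_accuracy(self, method):
        # cluster means ~9 pooled SDs apart: both methods must be near-perfect
        events, labels = _labeled_pair(separation=4.0)
        xtr, ytr, xte, yte = _split(events, labels)
        model = fit(ClassifierSpec(method, seed=0), xtr, ytr)
        report = evaluate_split(model, xte, yte)
        assert report.accuracy >= 0.99

    def test_deterministic_predictions(self, method):
        events, labels = _labeled_pair(separation=0.5, n=600)
        xtr, ytr, xte, _ = _split(events, labels)
        m1 = fit(ClassifierSpec(method, seed=5), xtr, ytr)
        m2 = fit(ClassifierSpec(method, seed=5), xtr, ytr)
        assert np.array_equal(predict_labels(m1, xte), predict_labels(m2, xte))

    def test_scores_normalized_and_argmax_consistent(self, method):
        events, labels = _labeled_pair(separation=0.5, n=600)
        xtr, ytr, xte, _ = _split(events, labels)
        model = fit(ClassifierSpec(method, seed=1), xtr, ytr)
        scores = predict_scores(model, xte)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)
        assert np.array_equal(
            model.classes[np.argmax(scores, axis=1)], predict_labels(model, xte)
        )

    def test_label_permutation_symmetry(self, method):
        events, labels = _labeled_pair(separation=1.0, n=600)
        xtr, ytr, xte, _ = _split(events, labels)
        mapping = {"a": "zeta", "b": "alpha"}
        renamed = np.array([mapping[y] for y in ytr], dtype=object)
        m1 = fit(ClassifierSpec(method, seed=2), xtr, ytr)
        m2 = fit(ClassifierSpec(method, seed=2), xtr, renamed)
        p1 = predict_labels(m1, xte)
        p2 = predict_labels(m2, xte)
        assert np.array_equal(np.array([mapping[y] for y in p1], dtype=object), p2)


class TestIdenticalDistributions:
    def test_no_signal_auc(self, identical_samples):
        """Held-out AUC sits at 0.5 +- 0.03 when the taxa are indistinguishable."""
        com = build_even_community(identical_samples, n_per_pop=5000, seed=0)
        split = split_train_test(com, seed=0)
        model = fit(ClassifierSpec("RF", seed=0), split.train_events, split.train_labels)
        report = evaluate_split(model, split.test_events, split.test_labels)
        assert report.n_test == 3000
        assert report.auc == pytest.approx(0.5, abs=0.03)


class TestRandomForestMechanics:
    def test_single_tree_scores_are_votes(self):
        events, labels = _labeled_pair(separation=0.5, n=400)
        model = fit(ClassifierSpec("RF", rf_n_trees=1, seed=0), events, labels)
        scores = predict_scores(model, events)
        assert set(np.unique(scores)) <= {0.0, 1.0}

    def test_scores_equal_per_tree_vote_fractions(self):
        events, labels = _labeled_pair(separation=0.5, n=400)
        model = fit(ClassifierSpec("RF", rf_n_trees=25, seed=3), events, labels)
        scores = predict_scores(model, events)
        votes = np.zeros_like(scores)
        X = events.values
        for tree in model.sk_model.estimators_:
            pred = np.argmax(tree.predict_proba(X), axis=1)
            votes[np.arange(len(X)), pred] += 1
        np.testing.assert_allclose(scores, votes / 25, atol=1e-12)

    def test_one_tree_forest_equals_its_tree(self):
        events, labels = _labeled_pair(separation=0.5, n=300)
        model = fit(
            ClassifierSpec("RF", rf_n_trees=1, rf_features_per_split=12, seed=4),
            events, labels,
        )
        tree = model.sk_model.estimators_[0]
        tree_pred = model.classes[np.argmax(tree.predict_proba(events.values), axis=1)]
        assert np.array_equal(predict_labels(model, events), tree_pred)


class TestLdaMechanics:
    def test_midpoint_of_mirrored_classes_scores_half(self):
        rng = np.random.default_rng(0)
        x_a = rng.normal(2.0, 1.0, (300, 4))
        # class b is the exact mirror image: the origin is equidistant
        events = EventMatrix(["c1", "c2", "c3", "c4"], np.vstack([x_a, -x_a]))
        labels = np.array(["a"] * 300 + ["b"] * 300, dtype=object)
        model = fit(ClassifierSpec("LDA"), events, labels)
        mid = EventMatrix(["c1", "c2", "c3", "c4"], np.zeros((1, 4)))
        np.testing.assert_allclose(predict_scores(model, mid)[0], [0.5, 0.5], atol=1e-6)


class TestContracts:
    def test_single_class_rejected(self):
        events, _ = _labeled_pair(0.5, n=50)
        with pytest.raises(ValueError, match="2 distinct"):
            fit(ClassifierSpec("LDA"), events, np.full(events.n_events, "a"))

    def test_channel_mismatch_lists_missing(self):
        events, labels = _labeled_pair(0.5, n=100)
        model = fit(ClassifierSpec("LDA"), events, labels)
        partial = EventMatrix(["FL1-A"], events.values[:, :1])
        with pytest.raises(ValueError, match="FL3-H"):
            predict_labels(model, partial)

    def test_empty_events_predict_empty(self):
        events, labels = _labeled_pair(0.5, n=100)
        model = fit(ClassifierSpec("RF", rf_n_trees=5), events, labels)
        empty = EventMatrix(list(CANONICAL_PANEL), np.empty((0, 12)))
        assert len(predict_labels(model, empty)) == 0
        with pytest.raises(ValueError, match="zero events"):
            estimate_composition(model, empty)

    def test_invalid_spec(self):
        with pytest.raises(ValueError, match="method"):
            ClassifierSpec("SVM")
        with pytest.raises(ValueError, match="rf_n_trees"):
            ClassifierSpec("RF", rf_n_trees=0)


class TestComposition:
    def test_plugin_arithmetic(self):
        events, labels = _labeled_pair(separation=4.0, n=600)
        model = fit(ClassifierSpec("RF", seed=0), events, labels)
        only_a = events.take(np.asarray(labels == "a"))
        estimate = estimate_composition(model, only_a)
        assert estimate.p_hat[0] >= 0.99  # essentially all predicted "a"
        assert estimate.counts.sum() == only_a.n_events

    def test_composition_equals_confusion_column_sums(self):
        """Plug-in counts == column sums of the raw confusion matrix (exact)."""
        events, labels = _labeled_pair(separation=0.8, n=500)
        xtr, ytr, xte, yte = _split(events, labels)
        model = fit(ClassifierSpec("RF", rf_n_trees=20, seed=1), xtr, ytr)
        estimate = estimate_composition(model, xte)
        cm = confusion_matrix(yte, predict_labels(model, xte), model.classes)
        assert np.array_equal(estimate.counts, cm.counts.sum(axis=0))
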