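"""End-to-end experiment orchestration.

Three experiments, each consuming a list of gated
:class:`~flowident.preprocessing.PopulationSample` (from real FCS/CSV folders
or the synthetic generator) and emitting tidy tables:

* pairwise scan — every pair of taxa becomes an even community; LDA and RF
  are trained/evaluated on IDENTICAL 70/30 splits, so classifier comparisons
  are paired. Summary: mean/SD of AUC and accuracy plus the fraction of
  communities above 0.90.
* richness scan — for each richness S, up to ``max_combinations`` taxon
  combinations (all of them when fewer exist) are built, split and scored;
  the per-S mean accuracy with a +-1 SD band is reported next to the 1/S
  random-guess baseline.
* gradient recovery — a classifier trained on a FULL even community (the
  gradient is the test set, so nothing is held out) predicts the composition
  of every gradient level; RMSE against the target gradient and D1 diversity
  with propagated confidence intervals complete the report. Training draws
  and gradient draws are disjoint whenever the pools allow.

All tables are bit-reproducible under a fixed root seed: per-task seeds are
derived by stable hashing (see :func:`flowident.community.derive_seed`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ClassifierSpec, estimate_composition, fit
from .community import (
    GRADIENT_LEVELS,
    build_even_community,
    build_gradient,
    derive_seed,
    enumerate_communities,
    split_train_test,
)
from .diversity import DEFAULT_EPSILON_I, d1_with_ci
from .evaluation import evaluate_split, rmse_gradient

__all__ = [
    "ExperimentConfig",
    "run_gradient_recovery",
    "run_pairwise_scan",
    "run_richness_scan",
    "write_outputs",
]

logger = logging.getLogger("flowident")


@dataclass
class ExperimentConfig:
    """Shared experiment parameters (defaults are the reference protocol)."""

    n_per_pop: int = 5000            # N_ax cells subsampled per axenic pool
    fraction_train: float = 0.70
    classifiers: tuple = ("LDA", "RF")
    rf_n_trees: int = 200
    max_combinations: int = 150      # per richness increment
    richness_values: tuple | None = None  # default: 2..n_taxa
    gradient_levels: tuple = GRADIENT_LEVELS
    n_total_gradient: int = 10000    # cells per gradient community
    epsilon_i: float = DEFAULT_EPSILON_I
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def spec(self, method: str, seed: int) -> ClassifierSpec:
        return ClassifierSpec(method=method, rf_n_trees=self.rf_n_trees, seed=seed)


def _fit_and_score(config, samples_pair_or_list, task_seed):
    """Build one even community, split it, score every classifier on it."""
    community = build_even_community(
        samples_pair_or_list, n_per_pop=config.n_per_pop,
        seed=derive_seed(task_seed, "build"),
    )
    split = split_train_test(
        community, fraction_train=config.fraction_train,
        seed=derive_seed(task_seed, "split"),
    )
    out = {}
    for method in config.classifiers:
        model = fit(
            config.spec(method, derive_seed(task_seed, "fit", method)),
            split.train_events, split.train_labels,
        )
        out[method] = (
            evaluate_split(model, split.test_events, split.test_labels),
            split,
        )
    return community, out


def run_pairwise_scan(samples, config: ExperimentConfig):
    """Score every pair of taxa; returns (per-pair table, summary table)."""
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("a pairwise scan needs at least 2 populations")
    by_id = {s.taxon_id: s for s in samples}
    pairs = enumerate_communities(list(by_id), S=2)
    rows = []
    for taxon_a, taxon_b in pairs:
        task_seed = derive_seed(config.seed, "pairwise", taxon_a, taxon_b)
        _, scored = _fit_and_score(config, [by_id[taxon_a], by_id[taxon_b]], task_seed)
        for method, (report, split) in scored.items():
            logger.info(
                "experiment=pairwise pair=%s/%s classifier=%s seed=%d "
                "n_train=%d n_test=%d auc=%.4f accuracy=%.4f",
                taxon_a, taxon_b, method, task_seed,
                len(split.train_labels), report.n_test, report.auc, report.accuracy,
            )
            rows.append(
                {
                    "taxon_a": taxon_a,
                    "taxon_b": taxon_b,
                    "classifier": method,
                    "auc": report.auc,
                    "accuracy": report.accuracy,
                    "n_train": len(split.train_labels),
                    "n_test": report.n_test,
                    "seed": task_seed,
                }
            )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("classifier")
        .agg(
            n_communities=("accuracy", "size"),
            mu_auc=("auc", "mean"),
            sigma_auc=("auc", "std"),
            frac_auc_gt_090=("auc", lambda s: float(np.mean(s > 0.90))),
            mu_acc=("accuracy", "mean"),
            sigma_acc=("accuracy", "std"),
            frac_acc_gt_090=("accuracy", lambda s: float(np.mean(s > 0.90))),
        )
        .reset_index()
    )
    return table, summary


def run_richness_scan(samples, config: ExperimentConfig):
    """Accuracy vs community richness; returns (per-community, per-S summary).

    The 68% band of the summary is mean +- 1 SD of the per-community
    accuracies at each S.
    """
    samples = list(samples)
    if len(samples) < 3:
        raise ValueError("a richness scan needs at least 3 populations")
    by_id = {s.taxon_id: s for s in samples}
    richness_values = config.richness_values or tuple(range(2, len(samples) + 1))
    rows = []
    for s_val in richness_values:
        combos = enumerate_communities(
            list(by_id), S=s_val,
            max_combinations=config.max_combinations,
            seed=derive_seed(config.seed, "richness-combos", s_val),
        )
        for combo in combos:
            task_seed = derive_seed(config.seed, "richness", s_val, *combo)
            _, scored = _fit_and_score(config, [by_id[t] for t in combo], task_seed)
            for method, (report, split) in scored.items():
                logger.info(
                    "experiment=richness S=%d community=%s classifier=%s seed=%d "
                    "n_train=%d n_test=%d accuracy=%.4f",
                    s_val, "+".join(combo), method, task_seed,
                    len(split.train_labels), report.n_test, report.accuracy,
                )
                rows.append(
                    {
                        "S": s_val,
                        "community": "+".join(combo),
                        "classifier": method,
                        "accuracy": report.accuracy,
                        "n_test": report.n_test,
                        "seed": task_seed,
                    }
                )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby(["S", "classifier"])
        .agg(
            n_communities=("accuracy", "size"),
            mean_accuracy=("accuracy", "mean"),
            sd_accuracy=("accuracy", lambda s: float(s.std(ddof=1)) if len(s) > 1 else 0.0),
        )
        .reset_index()
    )
    summary["band68_lo"] = summary["mean_accuracy"] - summary["sd_accuracy"]
    summary["band68_hi"] = summary["mean_accuracy"] + summary["sd_accuracy"]
    summary["baseline_random"] = 1.0 / summary["S"]
    return table, summary


def run_gradient_recovery(
    sample_a, sample_b, config: ExperimentConfig, gradient_samples=None
):
    """Train on a full even community, predict a gradient; returns tables.

    Returns ``(levels_table, rmse_table)``. The levels table carries, per
    level and classifier, the predicted first-population abundance and the
    D1 diversity of target and prediction with 68/95% CIs propagated from
    ``config.epsilon_i``. By default the gradient is drawn from the same
    pools as training but from disjoint events (where pool size permits);
    passing ``gradient_samples=(a, b)`` — e.g. a re-measured batch — draws
    the gradient from those pools instead.
    """
    root = derive_seed(config.seed, "gradient", sample_a.taxon_id, sample_b.taxon_id)
    training = build_even_community(
        [sample_a, sample_b], n_per_pop=config.n_per_pop,
        seed=derive_seed(root, "train-community"),
    )
    grad_a, grad_b = gradient_samples if gradient_samples else (sample_a, sample_b)
    # keep gradient draws disjoint from the training draws where pools allow
    exclude = {}
    if gradient_samples is None:
        needed = int(np.rint(max(config.gradient_levels) * config.n_total_gradient))
        for sample in (sample_a, sample_b):
            spent = training.meta["source_indices"][sample.taxon_id]
            if sample.pooled.n_events - len(spent) >= needed:
                exclude[sample.taxon_id] = spent
    gradient = build_gradient(
        grad_a, grad_b,
        levels=config.gradient_levels,
        n_total=config.n_total_gradient,
        seed=derive_seed(root, "gradient-draws"),
        exclude_indices=exclude,
    )

    rows, rmse_rows = [], []
    for method in config.classifiers:
        model = fit(
            config.spec(method, derive_seed(root, "fit", method)),
            training.events, training.labels,
        )
        idx_a = list(model.classes).index(sample_a.taxon_id)
        p_hat1 = []
        for level, communit in zip(gradient.levels, gradient.communities):
            estimate = estimate_composition(model, communit.events)
            p_hat1.append(float(estimate.p_hat[idx_a]))
        for level, p_hat in zip(gradient.levels, p_hat1):
            target = np.array([level, 1.0 - level])
            predicted = np.array([p_hat, 1.0 - p_hat])
            d1_target = d1_with_ci(target, config.epsilon_i)
            d1_pred = d1_with_ci(predicted, config.epsilon_i)
            rows.append(
                {
                    "taxon_a": sample_a.taxon_id,
                    "taxon_b": sample_b.taxon_id,
                    "classifier": method,
                    "level": level,
                    "p_hat1": p_hat,
                    "d1_target": d1_target.d1,
                    "d1_target_ci68_lo": d1_target.ci68[0],
                    "d1_target_ci68_hi": d1_target.ci68[1],
                    "d1_target_ci95_lo": d1_target.ci95[0],
                    "d1_target_ci95_hi": d1_target.ci95[1],
                    "d1_pred": d1_pred.d1,
                }
            )
        rmse = rmse_gradient(gradient.levels, p_hat1)
        logger.info(
            "experiment=gradient pair=%s/%s classifier=%s seed=%d levels=%d rmse=%.4f",
            sample_a.taxon_id, sample_b.taxon_id, method, root,
            len(gradient.levels), rmse,
        )
        rmse_rows.append(
            {
                "taxon_a": sample_a.taxon_id,
                "taxon_b": sample_b.taxon_id,
                "classifier": method,
                "rmse": rmse,
                "n_levels": len(gradient.levels),
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(rmse_rows)


def write_outputs(out_dir, tables: dict, summary: dict | None = None) -> Path:
    """Write named DataFrames as CSV plus an optional JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    if summary is not None:
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return out
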