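"""Construction of labeled in silico communities.

An in silico community aggregates events subsampled (without replacement)
from separately measured axenic-culture pools, so the population of origin of
every cell is known. Evenly composed communities (N_ax cells per taxon,
default 5,000) feed classifier training/evaluation; two-taxon abundance
gradients (default 13 levels from 1% to 99%, 10,000 cells per community)
probe composition recovery.

Every stochastic operation takes an explicit seed; :func:`derive_seed` maps a
root seed plus task tokens to stable per-task seeds.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .fcs_io import EventMatrix, concat_events
from .preprocessing import PopulationSample

__all__ = [
    "AbundanceGradient",
    "GRADIENT_LEVELS",
    "InSilicoCommunity",
    "SplitCommunity",
    "build_even_community",
    "build_gradient",
    "derive_seed",
    "enumerate_communities",
    "split_train_test",
]

#: Default relative-abundance levels of a two-population gradient.
GRADIENT_LEVELS = (
    0.01, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50,
    0.60, 0.70, 0.80, 0.90, 0.95, 0.99,
)


def derive_seed(root_seed: int, *tokens) -> int:
    """Stable sub-seed (< 2**31) from a root seed and task tokens."""
    key = "|".join([str(int(root_seed))] + [str(t) for t in tokens])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class InSilicoCommunity:
    """Labeled aggregation of subsampled events from S populations."""

    populations: list
    events: EventMatrix
    labels: np.ndarray
    target_composition: np.ndarray
    n_per_population: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.populations = [str(p) for p in self.populations]
        self.labels = np.asarray(self.labels)
        self.target_composition = np.asarray(self.target_composition, dtype=float)
        self.n_per_population = np.asarray(self.n_per_population, dtype=int)
        s = len(self.populations)
        if s < 2:
            raise ValueError("community richness S must be >= 2")
        if not (
            len(self.target_composition) == len(self.n_per_population) == s
        ):
            raise ValueError("populations, composition and counts must align")
        if abs(self.target_composition.sum() - 1.0) > 1e-9:
            raise ValueError("target composition must sum to 1")
        if np.any((self.target_composition < 0) | (self.target_composition > 1)):
            raise ValueError("composition entries must lie in [0, 1]")
        if self.labels.shape[0] != self.events.n_events:
            raise ValueError("one label per event required")
        for taxon, n in zip(self.populations, self.n_per_population):
            if int(np.sum(self.labels == taxon)) != int(n):
                raise ValueError(f"label multiset does not match counts for {taxon!r}")

    @property
    def richness(self) -> int:
        return len(self.populations)

    @property
    def n_total(self) -> int:
        return int(self.n_per_population.sum())

    @property
    def achieved_composition(self) -> np.ndarray:
        return self.n_per_population / max(1, self.n_total)


@dataclass
class SplitCommunity:
    """Disjoint train/test partition of a community's events."""

    train_events: EventMatrix
    train_labels: np.ndarray
    test_events: EventMatrix
    test_labels: np.ndarray
    fraction_train: float = 0.70


@dataclass
class AbundanceGradient:
    """One two-population community per target abundance level."""

    levels: list
    communities: list
    n_total_per_community: int

    def __post_init__(self) -> None:
        for level, community in zip(self.levels, self.communities):
            p = community.target_composition
            if abs(p[0] - level) > 1e-9 or abs(p[0] + p[1] - 1.0) > 1e-9:
                raise ValueError("gradient community composition inconsistent")


def _draw(pool: EventMatrix, n: int, rng: np.random.Generator, exclude=None):
    """Uniform draw of n distinct row indices from a pool, minus exclusions."""
    available = np.arange(pool.n_events)
    if exclude is not None and len(exclude):
        available = np.setdiff1d(available, np.asarray(exclude, dtype=int))
    if n > len(available):
        raise ValueError(f"requested {n} events but only {len(available)} available")
    return np.sort(rng.choice(available, size=n, replace=False))


def _assemble(samples, counts, indices_per_taxon) -> tuple:
    parts, labels = [], []
    for sample, n, idx in zip(samples, counts, indices_per_taxon):
        parts.append(sample.pooled.take(idx))
        labels.append(np.full(n, sample.taxon_id, dtype=object))
    events = concat_events(parts)
    return events, np.concatenate(labels) if labels else np.array([], dtype=object)


def build_even_community(
    samples,
    n_per_pop: int = 5000,
    seed: int = 0,
    allow_short: bool = False,
) -> InSilicoCommunity:
    """Evenly composed community: n_per_pop cells drawn per pooled sample.

    Draws are uniform without replacement and deterministic given ``seed``.
    A pool smaller than ``n_per_pop`` raises unless ``allow_short`` is set,
    in which case all available events are taken and the achieved composition
    is recorded as the target.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("an in silico community needs at least 2 populations")
    rng = np.random.default_rng(int(seed))
    counts, indices = [], []
    for sample in samples:
        n_avail = sample.pooled.n_events
        if n_avail < n_per_pop and not allow_short:
            raise ValueError(
                f"pool for {sample.taxon_id!r} holds {n_avail} events, "
                f"{n_per_pop - n_avail} short of n_per_pop={n_per_pop}"
            )
        take = min(n_per_pop, n_avail)
        counts.append(take)
        indices.append(_draw(sample.pooled, take, rng))
    counts = np.asarray(counts, dtype=int)
    events, labels = _assemble(samples, counts, indices)
    total = counts.sum()
    composition = (
        np.full(len(samples), 1.0 / len(samples))
        if counts.min() == counts.max()
        else counts / total
    )
    return InSilicoCommunity(
        populations=[s.taxon_id for s in samples],
        events=events,
        labels=labels,
        target_composition=composition,
        n_per_population=counts,
        meta={
            "seed": int(seed),
            "source_indices": {
                s.taxon_id: idx for s, idx in zip(samples, indices)
            },
        },
    )


def split_train_test(
    community: InSilicoCommunity,
    fraction_train: float = 0.70,
    seed: int = 0,
) -> SplitCommunity:
    """Stratified train/test split of a community.

    Per taxon, round(fraction_train * n_i) events go to training and the rest
    to test, so the per-taxon train share is within one event of the target
    fraction for any composition. Deterministic given ``seed``.
    """
    if not (0.0 < fraction_train < 1.0):
        raise ValueError("fraction_train must lie strictly between 0 and 1")
    if community.events.n_events == 0:
        raise ValueError("cannot split an empty community")
    rng = np.random.default_rng(int(seed))
    train_idx, test_idx = [], []
    for taxon in community.populations:
        idx = np.flatnonzero(community.labels == taxon)
        if idx.size == 0:
            continue
        perm = rng.permutation(idx)
        n_train = int(np.rint(fraction_train * idx.size))
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.sort(np.concatenate(test_idx))
    return SplitCommunity(
        train_events=community.events.take(train_idx),
        train_labels=community.labels[train_idx],
        test_events=community.events.take(test_idx),
        test_labels=community.labels[test_idx],
        fraction_train=fraction_train,
    )


def build_gradient(
    sample_a: PopulationSample,
    sample_b: PopulationSample,
    levels=GRADIENT_LEVELS,
    n_total: int = 10000,
    seed: int = 0,
    exclude_indices: dict | None = None,
) -> AbundanceGradient:
    """Two-population abundance gradient, one community per level.

    Per level, round-half-even(p1 * n_total) events of ``sample_a`` and the
    remainder of ``sample_b`` are drawn without replacement (independently
    across levels), so each community holds exactly ``n_total`` events.
    ``exclude_indices`` (taxon_id -> pool row indices) removes events already
    spent on, e.g., a training community, keeping train and test draws
    disjoint.
    """
    levels = [float(x) for x in levels]
    if any(not (0.0 <= x <= 1.0) for x in levels):
        raise ValueError("gradient levels must lie in [0, 1]")
    exclude_indices = exclude_indices or {}
    rng = np.random.default_rng(int(seed))
    communities = []
    for level in levels:
        n_a = int(np.rint(level * n_total))
        n_b = n_total - n_a
        idx_a = _draw(sample_a.pooled, n_a, rng, exclude_indices.get(sample_a.taxon_id))
        idx_b = _draw(sample_b.pooled, n_b, rng, exclude_indices.get(sample_b.taxon_id))
        events, labels = _assemble(
            [sample_a, sample_b], [n_a, n_b], [idx_a, idx_b]
        )
        communities.append(
            InSilicoCommunity(
                populations=[sample_a.taxon_id, sample_b.taxon_id],
                events=events,
                labels=labels,
                target_composition=np.array([level, 1.0 - level]),
                n_per_population=np.array([n_a, n_b]),
                meta={"seed": int(seed), "level": level},
            )
        )
    return AbundanceGradient(
        levels=levels, communities=communities, n_total_per_community=int(n_total)
    )


def enumerate_communities(taxa, S: int, max_combinations=None, seed: int = 0):
    """All (or a uniform sample of) S-taxon combinations.

    Returns sorted tuples without duplicates. When the number of
    combinations C(len(taxa), S) exceeds ``max_combinations``, a uniform
    random subset of that size is drawn (deterministic given ``seed``);
    otherwise ALL combinations are returned in lexicographic order.
    """
    taxa = sorted(str(t) for t in taxa)
    if not (2 <= S <= len(taxa)):
        raise ValueError(f"S must lie in [2, {len(taxa)}], got {S}")
    total = math.comb(len(taxa), S)
    if max_combinations is None or total <= max_combinations:
        return list(itertools.combinations(taxa, S))
    rng = np.random.default_rng(int(seed))
    if total <= 2_000_000:
        all_combos = list(itertools.combinations(taxa, S))
        chosen = rng.choice(total, size=max_combinations, replace=False)
        return sorted(all_combos[i] for i in chosen)
    # combination space too large to enumerate: rejection-sample distinct tuples
    chosen_set = set()
    while len(chosen_set) < max_combinations:
        combo = tuple(sorted(rng.choice(taxa, size=S, replace=False)))
        chosen_set.add(combo)
    return sorted(chosen_set)
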