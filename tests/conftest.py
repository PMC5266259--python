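"""Shared fixtures: synthetic panels are simulated once per session."""

import numpy as np
import pytest

from flowident import (
    EventMatrix,
    PopulationSample,
    default_gate,
    derive_seed,
    identical_pair,
    make_panel,
    preset_pairs,
    simulate_panel,
)

ROOT_SEED = 20170125


def toy_sample(taxon_id: str, n: int, seed: int = 0, channels=("IDX", "X")) -> PopulationSample:
    """Minimal pooled sample whose first channel is the pool row index.

    The index channel makes without-replacement draws verifiable by event
    identity.
    """
    rng = np.random.default_rng(seed)
    values = np.column_stack([np.arange(n, dtype=float), rng.uniform(0, 100, n)])
    pooled = EventMatrix(list(channels), values)
    return PopulationSample(
        taxon_id=taxon_id, replicates=[pooled], gate=default_gate(), pooled=pooled
    )


@pytest.fixture(scope="session")
def preset_samples():
    """Gated pooled samples for the low/medium/high separability pairs.

    Pools hold ~17,000 gated events per taxon: enough for a full 5,000-cell
    even training community plus disjoint 10,000-cell gradient draws.
    """
    out = {}
    for name, models in preset_pairs(n_events=9000).items():
        dataset = simulate_panel(
            list(models), replicates=2, seed=derive_seed(ROOT_SEED, "preset", name)
        )
        out[name] = dataset.samples()
    return out


@pytest.fixture(scope="session")
def identical_samples():
    models = identical_pair(n_events=9000)
    dataset = simulate_panel(
        list(models), replicates=2, seed=derive_seed(ROOT_SEED, "identical")
    )
    return dataset.samples()


@pytest.fixture(scope="session")
def ten_taxon_samples():
    """A 10-population panel with mixed pairwise separability."""
    models = make_panel(10, n_events=2400, spread=0.6, seed=ROOT_SEED)
    dataset = simulate_panel(models, replicates=2, seed=derive_seed(ROOT_SEED, "panel10"))
    return dataset.samples()


@pytest.fixture(scope="session")
def small_panel_samples():
    """Four small populations for quick experiment-orchestration tests."""
    models = make_panel(4, n_events=900, spread=0.8, seed=7)
    dataset = simulate_panel(models, replicates=2, seed=derive_seed(7, "panel4"))
    return dataset.samples()
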