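import numpy as np
import pandas as pd
import pytest

from nzip.read_processing import CountTable
from nzip.simulate import SimConfig, simulate_counts


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_truth(n_tiles, effects=None, baseline=None, seed=0):
    """Minimal per-tile truth frame for direct count simulation."""
    rng = np.random.default_rng(seed)
    eff = np.zeros(n_tiles) if effects is None else np.asarray(effects, dtype=float)
    base = rng.lognormal(0, 1, n_tiles) if baseline is None else np.asarray(baseline)
    return pd.DataFrame(
        {
            "sequence": ["A"] * n_tiles,
            "n_let7": 0,
            "max_au": 0,
            "effect": eff,
            "baseline": base,
        },
        index=[f"tile{i:04d}" for i in range(n_tiles)],
    )


@pytest.fixture
def small_count_table():
    """300 tiles, triplicate neurite/soma, 30 tiles with log2FC = 2."""
    effects = np.zeros(300)
    effects[:30] = 2.0
    truth = make_truth(300, effects=effects, seed=42)
    cfg = SimConfig(depth=2e5, dispersion=0.05, replicates=3, seed=42)
    table = simulate_counts(truth, cfg, np.random.default_rng(42))
    return table, truth


@pytest.fixture
def tiny_table():
    counts = pd.DataFrame(
        {
            "s_soma_1": [100, 10, 50],
            "s_soma_2": [110, 12, 55],
            "n_neu_1": [100, 40, 50],
            "n_neu_2": [105, 44, 52],
        },
        index=["a", "b", "c"],
    )
    samples = pd.DataFrame(
        {
            "compartment": ["soma", "soma", "neurite", "neurite"],
            "replicate": ["1", "2", "1", "2"],
            "condition": ["control"] * 4,
        },
        index=counts.columns,
    )
    return CountTable(counts, samples)
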