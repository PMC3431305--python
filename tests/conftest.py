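"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

import metaboprof as mp
from metaboprof.synthetic import SimulationConfig, simulate_feature_table


@pytest.fixture(scope="session")
def small_sim():
    """Synthetic study at reduced feature count (fast): table + ground truth."""
    cfg = SimulationConfig(seed=0, n_features=300)
    table, truth = simulate_feature_table(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def filtered(small_sim):
    """Replicate-averaged, presence- and mean-filtered table."""
    _, table, _ = small_sim
    avg = mp.average_replicates(table)
    ft, _ = mp.filter_presence(avg)
    ft, _ = mp.filter_mean_intensity(ft)
    return ft


@pytest.fixture(scope="session")
def scaled(filtered):
    """Pareto-scaled matrix + class labels of the filtered table."""
    X, _ = mp.pareto_scale(filtered)
    return X, filtered.class_labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
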