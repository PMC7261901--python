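import numpy as np
import pandas as pd
import pytest

from cernet import SimulationConfig, simulate_study, simulate_target_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_mrna=60, n_lncrna=25, n_mirna=18,
                            n_per_group=10, de_fraction=0.2, de_log2fc=1.5,
                            dispersion=0.05, n_cerna_triples=3,
                            sponge_strength=0.9, decoy_target_fraction=0.1,
                            seed=7)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_targets(small_config, small_study):
    return simulate_target_table(small_study.truth, small_config)


def random_adjacency(rng, n):
    """Random valid soft adjacency: symmetric, [0,1], zero diagonal."""
    A = rng.uniform(0.0, 1.0, size=(n, n))
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 0.0)
    labels = [f"g{i}" for i in range(n)]
    return pd.DataFrame(A, index=labels, columns=labels)
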