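import numpy as np
import pytest

from infodyn.community import CommunityConfig, simulate_base
from infodyn.tables import AnalysisConfig


@pytest.fixture(scope="session")
def base_ts():
    """One base-scenario community run shared across tests."""
    return simulate_base(CommunityConfig(rng_seed=0))


@pytest.fixture()
def fast_config():
    """Analysis profile with reduced averaging for quick tests."""
    return AnalysisConfig(n_estimation_runs=3, n_surrogates=20, rng_seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def ar_coupled_pair(T: int, seed: int, coupling: float = 0.5):
    """Two coupled Gaussian AR(1) processes: x driven by y with one-step lag."""
    rng = np.random.default_rng(seed)
    x = np.zeros(T)
    y = np.zeros(T)
    for t in range(1, T):
        y[t] = 0.6 * y[t - 1] + rng.normal()
        x[t] = 0.4 * x[t - 1] + coupling * y[t - 1] + rng.normal()
    return x, y


def binary_markov_chain(T: int, seed: int, p_stay1: float = 0.8, p_up0: float = 0.3):
    """A two-state Markov chain with tunable transition probabilities."""
    rng = np.random.default_rng(seed)
    x = np.zeros(T, dtype=np.int64)
    for t in range(1, T):
        p = p_stay1 if x[t - 1] == 1 else p_up0
        x[t] = int(rng.random() < p)
    return x
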