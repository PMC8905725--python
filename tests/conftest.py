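import numpy as np
import pytest

from entrocell.entropy import CoefficientCache
from entrocell.simulate import SyntheticTrajectoryConfig, simulate_trajectory


@pytest.fixture(scope="session")
def cache():
    """One shared BUB coefficient cache (solves are deterministic)."""
    return CoefficientCache()


@pytest.fixture(scope="session")
def small_trajectory_config():
    """Reduced trajectory used throughout the suite: 600 cells, 420 genes."""
    return SyntheticTrajectoryConfig(
        n_cells=600,
        n_switch_genes=60,
        n_housekeeping_genes=60,
        n_noise_genes=300,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_trajectory(small_trajectory_config):
    return simulate_trajectory(small_trajectory_config)


def brute_force_plugin(counts):
    """Literal plugin formula from the empirical level frequencies."""
    counts = np.asarray(counts)
    N = len(counts)
    H = 0.0
    for level in np.unique(counts):
        p = np.sum(counts == level) / N
        H -= p * np.log(p)
    return H
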