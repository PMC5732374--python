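import numpy as np
import pytest

from rfclue import SimulationConfig, simulate_populations


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_sim():
    """Three well-separated populations, desk-sized (45 x 200)."""
    cfg = SimulationConfig(3, 15, 200, fst=0.3, seed=11)
    g, truth = simulate_populations(cfg)
    return g, truth


@pytest.fixture(scope="session")
def two_pop_sim():
    """Two populations at moderate divergence (60 x 300)."""
    cfg = SimulationConfig(2, 30, 300, fst=0.3, seed=5)
    g, truth = simulate_populations(cfg)
    return g, truth
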