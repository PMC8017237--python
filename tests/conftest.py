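import numpy as np
import pytest

from finchdev import SimulationConfig, default_design
from finchdev.simulate import simulate_dataset


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def small_dataset(design):
    """A small but complete synthetic study shared across test modules."""
    cfg = SimulationConfig(n_genes=200, seed=11)
    return simulate_dataset(cfg, design)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
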