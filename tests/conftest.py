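import numpy as np
import pytest

from xdp_progression import SimulationConfig, build_default_catalogue, simulate_cohort


@pytest.fixture(scope="session")
def catalogue():
    return build_default_catalogue()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort shared by read-only tests."""
    config = SimulationConfig(n_symptomatic=10, n_presymptomatic=2, n_negative=8, seed=101)
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231)
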