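import numpy as np
import pytest
from hypothesis import settings

from methylcause.simcohort import SimulationConfig, simulate_cohort

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """One moderately sized cohort shared across read-only tests."""
    cfg = SimulationConfig(n_individuals=1200, n_sites=300, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
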