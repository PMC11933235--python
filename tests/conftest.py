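import numpy as np
import pytest

from turntaking.synthetic_data import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A small full synthetic study reused across pipeline tests."""
    cfg = SimConfig(seed=11, n_individuals=10, n_interactions=30)
    return simulate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
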