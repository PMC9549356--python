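import numpy as np
import pytest

from greenwalk.cohort_simulator import TruthConfig
from greenwalk.synthetic_world import WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A compact 400 m x 400 m study area shared across tests."""
    cfg = WorldConfig(width=400, height=400, street_spacing=100)
    return generate_world(cfg, seed=17)


@pytest.fixture(scope="session")
def truth():
    return TruthConfig.default()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
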