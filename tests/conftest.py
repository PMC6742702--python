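import numpy as np
import pytest

from gcfb.config import GCConfig
from gcfb.fixtures import mini_config


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def default_cfg():
    return GCConfig()


@pytest.fixture
def mini_cfg():
    return mini_config()


@pytest.fixture(scope="session")
def mini_run():
    """One 3-day miniature GC run shared by integration-level checks."""
    from gcfb.engine import Simulation

    sim = Simulation(mini_config(), seed=7, record_transitions=True)
    ts = sim.run()
    return sim, ts
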