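import numpy as np
import pytest

import ovsim


@pytest.fixture(scope="session")
def params():
    return ovsim.default_parameters()


@pytest.fixture(scope="session")
def short_run(params):
    """A 120-day unstimulated run shared by event/trajectory tests."""
    cfg = ovsim.SimulationConfig(t_end=120.0, seed=7)
    return ovsim.simulate(params, config=cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
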