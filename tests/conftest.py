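import numpy as np
import pytest

import impedadapt as ia
from impedadapt.experiments import CENTER, _reach_plans


@pytest.fixture(scope="session")
def cfg():
    return ia.default_config()


@pytest.fixture(scope="session")
def reach(cfg):
    """One 12 cm, 300 ms reach straight ahead with a 100 ms hold."""
    return ia.reach_plan(CENTER, CENTER + [0.0, 0.12], 0.3, cfg, hold=0.1)


@pytest.fixture(scope="session")
def reaches8(cfg):
    return _reach_plans(cfg, CENTER, 8, 0.12, 0.3, 0.1)


@pytest.fixture(scope="session")
def small_net(cfg, reaches8):
    """Unweighted network clustered on the eight-reach state data."""
    from impedadapt.experiments import states_from_plans

    return ia.select_network(states_from_plans(reaches8), cfg.rbf, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
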