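import numpy as np
import pytest

from albupet.physiology import load_physiology_table
from albupet.simulate import SimulationConfig
from albupet.simulate.plasma import model_from_config


@pytest.fixture(scope="session")
def config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def physiology():
    return load_physiology_table()


@pytest.fixture(scope="session")
def plasma_model(config):
    return model_from_config(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
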