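import numpy as np
import pytest

from flits import InstrumentConfig
from flits.sensor import default_sensor_model


@pytest.fixture(scope="session")
def config():
    return InstrumentConfig()


@pytest.fixture(scope="session")
def in_situ_model():
    return default_sensor_model("in_situ")


@pytest.fixture(scope="session")
def in_vitro_model():
    return default_sensor_model("in_vitro")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
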