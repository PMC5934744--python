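import numpy as np
import pytest
from hypothesis import settings

from oxysim import PlasmaParams, SecretionParams, SpikingParams

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spiking_params():
    return SpikingParams()


@pytest.fixture(scope="session")
def secretion_params():
    return SecretionParams()


@pytest.fixture(scope="session")
def plasma_params():
    return PlasmaParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
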