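import numpy as np
import pytest

from autoreg.mfari import calibrate
from autoreg.tiecks import make_templates


@pytest.fixture(scope="session")
def templates_5hz():
    """The ten canonical grading templates at the TFA rate."""
    return make_templates(5.0)


@pytest.fixture(scope="session")
def templates_2hz():
    return make_templates(2.0)


@pytest.fixture(scope="session")
def calibration_5hz(templates_5hz):
    return calibrate(templates_5hz)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
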