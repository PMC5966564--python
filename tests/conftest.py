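import numpy as np
import pytest

from nirsbci.hemodynamics import DeviceProfile
from nirsbci.macd import MacdConfig
from nirsbci.protocol import build_timeline, generate_trial_sequence


@pytest.fixture
def sim16():
    return DeviceProfile.sim16()


@pytest.fixture
def flight4():
    return DeviceProfile.flight4()


@pytest.fixture
def macd2hz():
    return MacdConfig(sampling_rate=2.0)


@pytest.fixture
def protocol20():
    """Standard 20-trial session laid out on the default timing."""
    sequence = generate_trial_sequence(10, seed=np.random.default_rng(7))
    return build_timeline(sequence)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
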