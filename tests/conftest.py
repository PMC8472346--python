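import numpy as np
import pytest

from emdecode.preprocess import Epochs
from emdecode.synth import NoiseModel, three_source_spec

FS = 200.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def times_2s():
    return np.arange(int(2 * FS)) / FS


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down three-source simulation for fast integration tests."""
    return three_source_spec(
        n_sensors=24, n_trials_per_condition=8, n_participants=3
    )


@pytest.fixture(scope="session")
def noiseless_spec():
    return three_source_spec(
        n_sensors=24,
        n_trials_per_condition=4,
        n_participants=2,
        noise=NoiseModel(sensor_white_sd=0.0, background_scale=0.0),
    )


@pytest.fixture
def sine_epochs():
    """2 trials x 2 channels of a pure 3 Hz tone, 221 samples at 200 Hz."""
    t = np.arange(221) / FS
    x = np.sin(2 * np.pi * 3 * t)
    data = np.tile(x, (2, 2, 1))
    return Epochs(data=data, fs=FS, tmin=-100.0, labels=np.array(["a", "b"]))
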