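import numpy as np
import pytest

import semgkit as sk
from semgkit.recording import EmgRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """Two 30-frame trials (labels 1 and 2) of a 3-channel recording at 100 Hz."""
    data = rng.normal(size=(60, 3))
    labels = np.repeat([1, 2], 30)
    trial_id = np.repeat([0, 1], 30)
    return EmgRecording(data=data, rate=100.0, labels=labels, trial_id=trial_id)


@pytest.fixture(scope="session")
def fixture_dataset():
    """The default 4-class synthetic dataset (10 channels, 100 Hz,
    10 trials per class, 3 s trials, amplitude + correlation structure)."""
    specs = sk.simulate.default_gesture_specs(4, 10, kind="both")
    return sk.simulate_dataset(specs, sk.SimConfig(seed=1))


@pytest.fixture(scope="session")
def channel_sequence_10():
    return sk.build_channel_sequence(10)
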