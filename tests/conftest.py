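import numpy as np
import pytest

from tgdecode import EpochsArray


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_epochs(n_trials=20, n_sensors=4, n_samples=60, fs=300.0, seed=0,
                condition="perception", data=None, labels=None):
    rng = np.random.default_rng(seed)
    if data is None:
        data = rng.standard_normal((n_trials, n_sensors, n_samples))
    else:
        data = np.asarray(data, dtype=float)
        n_trials, n_sensors, n_samples = data.shape
    if labels is None:
        labels = np.arange(n_trials) % 2
    times = np.arange(n_samples) / fs - 0.1
    return EpochsArray(data=data, labels=labels, times=times, fs=fs,
                       condition=condition, subject_id="T01")


@pytest.fixture
def epochs():
    return make_epochs()
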