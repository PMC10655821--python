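import numpy as np
import pytest

from meadev.core import RecordingMeta, SpikeTrain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_train(times, duration=60.0, amplitudes=None, electrode=1, **meta):
    times = np.asarray(times, dtype=float)
    if amplitudes is not None and np.isscalar(amplitudes):
        amplitudes = np.full(times.size, float(amplitudes))
    return SpikeTrain(times=times, duration=duration, amplitudes=amplitudes,
                      meta=RecordingMeta(electrode=electrode, **meta))


@pytest.fixture
def train_factory():
    return make_train
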