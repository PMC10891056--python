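import numpy as np
import pytest

from affectpipe.core import CHANNELS, RawRecording


def make_recording(samples, fs=256.0, participant_id="P01", stage="A"):
    """RawRecording from a (4, n) array (lists accepted)."""
    samples = np.asarray(samples, dtype=float)
    ts = np.arange(samples.shape[1]) / fs
    return RawRecording(participant_id, stage, fs, ts, samples)


def tone_recording(freq, amplitude=1.0, duration=4.0, fs=256.0, channel=None):
    """Pure sinusoid on one channel (or all channels if channel is None)."""
    n = int(duration * fs)
    t = np.arange(n) / fs
    tone = amplitude * np.sin(2 * np.pi * freq * t)
    samples = np.zeros((len(CHANNELS), n))
    if channel is None:
        samples[:] = tone
    else:
        samples[CHANNELS.index(channel)] = tone
    return make_recording(samples, fs=fs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
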