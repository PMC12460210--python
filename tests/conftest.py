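import numpy as np
import pytest

from netlearn import EEGRecording, sliding_windows


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def sinusoid_recording(freqs_and_phases, fs=512.0, duration=104.0,
                       labels=None):
    """Recording whose channels are pure sinusoids: one (freq, phase)
    pair per channel."""
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    data = np.stack(
        [np.sin(2 * np.pi * f * t + ph) for f, ph in freqs_and_phases]
    )
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(len(freqs_and_phases)))
    return EEGRecording(data=data, fs=fs, channel_labels=labels)


@pytest.fixture
def zero_lag_windows():
    """Two identical 10 Hz channels, 4 s / 2 s windows."""
    rec = sinusoid_recording([(10.0, 0.0), (10.0, 0.0)])
    return sliding_windows(rec)


@pytest.fixture
def quarter_cycle_windows():
    """sin vs cos at 10 Hz (constant 90 degree lag)."""
    rec = sinusoid_recording([(10.0, 0.0), (10.0, np.pi / 2)])
    return sliding_windows(rec)
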