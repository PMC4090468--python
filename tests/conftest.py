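import numpy as np
import pytest

from spredict.signal_io import Recording, Segment, SeizureAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone_segment():
    """6-channel, 10 s window of distinct tones at 256 Hz."""
    fs = 256.0
    t = np.arange(2560) / fs
    data = np.column_stack(
        [10.0 * np.cos(2 * np.pi * f * t + 0.3 * j) for j, f in enumerate([6, 7, 8, 9, 10, 12])]
    )
    return Segment(start_s=0.0, data=data, fs=fs)


@pytest.fixture
def flat_recording():
    """Featureless 2-channel recording for plumbing tests."""
    rng = np.random.default_rng(7)
    fs = 64.0
    data = rng.standard_normal((int(fs * 600), 2))
    return Recording(data=data, fs=fs, patient_id="flat")


def make_recording(duration_s, fs=64.0, d=2, onsets_s=(), ictal_len_s=30.0, seed=0):
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((int(round(duration_s * fs)), d))
    anns = [SeizureAnnotation(o, o + ictal_len_s) for o in onsets_s]
    return Recording(data=data, fs=fs, annotations=anns)
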