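import numpy as np
import pytest

from pupilsync.containers import PupilTrace, SessionDesign, TapTrial


def make_trace(values, sample_rate_hz=500.0, valid=None, t0_ms=0.0):
    """Build a uniformly sampled trace from raw values."""
    values = np.asarray(values, dtype=float)
    t = t0_ms + np.arange(values.size) * 1000.0 / sample_rate_hz
    if valid is None:
        valid = np.ones(values.size, dtype=bool)
    return PupilTrace(t, values, sample_rate_hz, np.asarray(valid, dtype=bool))


@pytest.fixture
def paced_trial():
    """60 exact cues at 500 ms with taps 30 ms ahead of every cue."""
    design = SessionDesign("P01", "T01", "Tap", "SMT", n_cues=60,
                           stimulus_onset_ms=1500.0)
    cues = 1500.0 + 500.0 * np.arange(60)
    return TapTrial(cues, cues - 30.0, design=design, iti_ms=500.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
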