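import numpy as np
import pytest

from hgt import SignalRecord, SynthSpec, estimate_rr, make_ppg_surrogate


@pytest.fixture(scope="session")
def surrogate_12bpm():
    """Noiseless 60-s PPG surrogate breathing at 12 bpm, with its estimate."""
    rec, schedule = make_ppg_surrogate(SynthSpec(rr_bpm=12.0))
    return rec, schedule, estimate_rr(rec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20231)


@pytest.fixture()
def tone_record():
    """Pure 0.2 Hz unit tone, 60 s at 100 Hz."""
    t = np.arange(6000) / 100.0
    return SignalRecord(np.cos(2 * np.pi * 0.2 * t), 100.0, label="tone")
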