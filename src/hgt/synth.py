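"""Synthetic physiological signals with known respiratory ground truth.

The generator emulates the structure the estimator relies on: a cardiac-band
oscillation (default 1.2 Hz, 72 bpm) whose amplitude and baseline are
modulated by a respiratory oscillation in the 0.09-0.35 Hz band, optional
paced-breathing rate changes mid-record, and additive white Gaussian noise at
a specified SNR.  Waveforms are sinusoidal surrogates, not beat-morphology
templates: sufficient to exercise decomposition, instantaneous-frequency
tracking and candidate screening while keeping the ground truth analytic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal import SignalRecord

__all__ = ["SynthSpec", "make_resp", "make_ppg_surrogate", "add_awgn"]

Schedule = list[tuple[float, float]]  # [(start_s, rr_bpm), ...]


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a surrogate record.

    ``rr_bpm`` is either a constant rate or a piecewise-constant schedule of
    ``(start_s, rr_bpm)`` segments (first start must be 0).  ``am_depth`` is
    the fractional respiratory amplitude modulation of the cardiac component;
    ``baseline_gain`` the additive respiratory baseline wander.  ``snr_db``
    of ``None`` means noiseless.
    """

    fs: float = 100.0
    duration: float = 60.0
    cardiac_freq: float = 1.2
    rr_bpm: float | Schedule = 12.0
    am_depth: float = 0.3
    baseline_gain: float = 0.5
    snr_db: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 2 * self.cardiac_freq:
            raise ValueError("fs must exceed twice the cardiac frequency")
        if not 0 <= self.am_depth < 1:
            raise ValueError(f"am_depth must lie in [0, 1), got {self.am_depth}")
        for _, rr in self.schedule:
            if not 0 < rr < 60 * self.fs / 2:
                raise ValueError(f"scheduled rate {rr} bpm not representable at fs={self.fs}")

    @property
    def schedule(self) -> Schedule:
        """Rate schedule normalized to list form."""
        if isinstance(self.rr_bpm, (int, float)):
            return [(0.0, float(self.rr_bpm))]
        sched = [(float(t), float(r)) for t, r in self.rr_bpm]
        if not sched or sched[0][0] != 0.0:
            raise ValueError("schedule must start at t=0")
        if any(t1 >= t2 for (t1, _), (t2, _) in zip(sched, sched[1:])):
            raise ValueError("schedule start times must be strictly increasing")
        return sched

    @property
    def n(self) -> int:
        return int(round(self.fs * self.duration))


def _rate_track(spec: SynthSpec) -> np.ndarray:
    """Per-sample respiration frequency in Hz from the schedule."""
    t = np.arange(spec.n) / spec.fs
    f = np.empty(spec.n)
    for start, rr in spec.schedule:
        f[t >= start] = rr / 60.0
    return f


def make_resp(spec: SynthSpec) -> SignalRecord:
    """Unit-amplitude respiratory sinusoid with phase-continuous rate changes.

    The phase integrates the scheduled instantaneous frequency, so a
    mid-record pace change produces no amplitude jump.
    """
    f = _rate_track(spec)
    phase = 2.0 * np.pi * np.cumsum(f) / spec.fs
    return SignalRecord(np.sin(phase), spec.fs, label="resp")


def make_ppg_surrogate(spec: SynthSpec) -> tuple[SignalRecord, Schedule]:
    """Respiration-modulated cardiac surrogate plus its ground-truth schedule.

    ``s(t) = (1 + am_depth * resp(t)) * cos(2 pi f_c t) + baseline_gain * resp(t)``,
    with AWGN appended when ``snr_db`` is set.  Modulation and baseline both
    carry the respiratory frequency, mirroring how respiration imprints on
    PPG and SCG.
    """
    resp = make_resp(spec).samples
    t = np.arange(spec.n) / spec.fs
    s = (1.0 + spec.am_depth * resp) * np.cos(2.0 * np.pi * spec.cardiac_freq * t)
    s = s + spec.baseline_gain * resp
    rec = SignalRecord(s, spec.fs, label="ppg_surrogate")
    if spec.snr_db is not None:
        rec = add_awgn(rec, spec.snr_db, spec.seed)
    return rec, spec.schedule


def add_awgn(signal: SignalRecord, snr_db: float, seed: int) -> SignalRecord:
    """Add white Gaussian noise at the requested SNR (dB) relative to signal power."""
    x = signal.samples
    power = float(np.mean(x**2))
    if power == 0.0:
        raise ValueError("cannot set an SNR relative to a zero-power signal")
    noise_var = power / (10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, np.sqrt(noise_var), x.size)
    return SignalRecord(x + noise, signal.fs, signal.label)
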