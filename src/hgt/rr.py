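"""Respiratory-rate estimation from decomposed IMFs.

The respiratory component is identified among the IMFs by its instantaneous
frequency statistics: candidates are the IMFs whose mean instantaneous
frequency lies in the physiologic respiration band (0.09-0.35 Hz by default,
i.e. 5.4-21 bpm); when several qualify, the one with the smallest IF standard
deviation wins — controlled breathing produces a narrow IF track, whereas
cardiac and noise modes wander.  RR in breaths per minute is 60 times the
selected IMF's mean instantaneous frequency.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .decompose import GafdConfig, gafd
from .hilbert import AnalyticImf, analytic_signal
from .signal import SignalRecord

__all__ = [
    "RrBand",
    "IfSummary",
    "RrEstimate",
    "RrStatus",
    "summarize_if",
    "screen_candidates",
    "select_respiratory",
    "estimate_rr",
    "estimate_rr_windowed",
    "num_windows",
    "min_duration_s",
]

#: Suggested minimum record length for a stable estimate, seconds.
SUGGESTED_MIN_DURATION_S = 20.0


@dataclass(frozen=True)
class RrBand:
    """Admissible respiration-frequency band, inclusive on both ends."""

    lower_hz: float = 0.09
    upper_hz: float = 0.35

    def __post_init__(self) -> None:
        if not 0 < self.lower_hz < self.upper_hz:
            raise ValueError(f"need 0 < lower < upper, got {self.lower_hz}, {self.upper_hz}")

    @property
    def lower_bpm(self) -> float:
        return 60.0 * self.lower_hz

    @property
    def upper_bpm(self) -> float:
        return 60.0 * self.upper_hz


def min_duration_s(band: RrBand) -> float:
    """Shortest record covering one full cycle at the slowest admissible rate."""
    return 1.0 / band.lower_hz


@dataclass(frozen=True)
class IfSummary:
    """Mean and standard deviation of one IMF's instantaneous frequency."""

    imf_index: int
    mean_freq: float  # Hz, plain mean over all N samples
    std_freq: float  # Hz, sample standard deviation (N-1 denominator)


class RrStatus(str, Enum):
    OK = "ok"
    NO_CANDIDATE = "no_candidate"


@dataclass(frozen=True)
class RrEstimate:
    """Outcome of the screening/selection rule for one record or window."""

    rr_bpm: float  # NaN when no candidate
    selected_imf: int | None
    candidates: list[IfSummary]
    band: RrBand
    status: RrStatus
    summaries: list[IfSummary] = field(default_factory=list)  # all IMFs, diagnostics


def summarize_if(analytic: AnalyticImf, trim: int = 0) -> IfSummary:
    """Mean and (N-1)-denominator standard deviation of the IF track.

    By default all N samples enter the statistics, boundary samples included.
    ``trim`` drops that many samples from each end first — an opt-in guard
    against analytic-signal edge distortion on short windows.
    """
    f = analytic.inst_freq
    if trim < 0 or 2 * trim >= f.size - 1:
        raise ValueError(f"trim of {trim} leaves too few of {f.size} samples")
    if trim:
        f = f[trim:-trim]
    if f.size < 2:
        raise ValueError("need at least 2 instantaneous-frequency samples")
    return IfSummary(
        imf_index=analytic.index,
        mean_freq=float(np.mean(f)),
        std_freq=float(np.std(f, ddof=1)),
    )


def screen_candidates(summaries: list[IfSummary], band: RrBand) -> list[IfSummary]:
    """Keep IMFs whose mean IF lies inside the band (inclusive), order preserved."""
    return [s for s in summaries if band.lower_hz <= s.mean_freq <= band.upper_hz]


def select_respiratory(candidates: list[IfSummary]) -> IfSummary:
    """Resolve multiple candidates by minimum IF standard deviation.

    Ties break toward the lower IMF index, which makes the rule deterministic.
    """
    if not candidates:
        raise ValueError("no candidate IMFs to select from")
    return min(candidates, key=lambda s: (s.std_freq, s.imf_index))


def estimate_rr(
    signal: SignalRecord,
    config: GafdConfig | None = None,
    band: RrBand | None = None,
    edge_trim_s: float = 0.0,
) -> RrEstimate:
    """Full pipeline: decompose, Hilbert-analyze, screen, select, convert to bpm.

    The record must span at least one cycle of the slowest admissible
    respiration (``1 / band.lower_hz`` seconds, 11.11 s for the default
    0.09 Hz bound); shorter inputs are refused.  Records under 20 s are
    accepted with a warning — the estimate is less stable.

    ``edge_trim_s`` optionally excludes that many seconds of the IF track at
    each end from the screening statistics; the default of 0 keeps the plain
    all-samples mean.
    """
    band = band if band is not None else RrBand()
    need = min_duration_s(band)
    if signal.duration < need:
        raise ValueError(
            f"record of {signal.duration:.2f} s cannot contain one full respiration "
            f"cycle at the band's lower bound {band.lower_hz} Hz; "
            f"at least {need:.2f} s are required"
        )
    if signal.duration < SUGGESTED_MIN_DURATION_S:
        warnings.warn(
            f"record of {signal.duration:.2f} s is shorter than the suggested "
            f"{SUGGESTED_MIN_DURATION_S:.0f} s; the estimate may be unstable",
            RuntimeWarning,
            stacklevel=2,
        )

    dec = gafd(signal, config)
    trim = int(round(edge_trim_s * signal.fs))
    summaries = [
        summarize_if(analytic_signal(imf, signal.fs, index=k + 1), trim=trim)
        for k, imf in enumerate(dec.imfs)
    ]
    candidates = screen_candidates(summaries, band)
    if not candidates:
        return RrEstimate(
            rr_bpm=math.nan,
            selected_imf=None,
            candidates=[],
            band=band,
            status=RrStatus.NO_CANDIDATE,
            summaries=summaries,
        )
    chosen = select_respiratory(candidates)
    return RrEstimate(
        rr_bpm=60.0 * chosen.mean_freq,
        selected_imf=chosen.imf_index,
        candidates=candidates,
        band=band,
        status=RrStatus.OK,
        summaries=summaries,
    )


def num_windows(duration_s: float, window_s: float) -> int:
    """Number of complete non-overlapping windows in a record (floor rule)."""
    if window_s <= 0:
        raise ValueError(f"window length must be positive, got {window_s}")
    return int(duration_s / window_s + 1e-12)


def estimate_rr_windowed(
    signal: SignalRecord,
    window_s: float = 20.0,
    config: GafdConfig | None = None,
    band: RrBand | None = None,
    edge_trim_s: float = 0.0,
) -> list[tuple[float, RrEstimate]]:
    """One RR estimate per non-overlapping window; trailing partial dropped.

    Returns ``(window start in seconds, estimate)`` pairs in time order.
    """
    band = band if band is not None else RrBand()
    if window_s < min_duration_s(band):
        raise ValueError(
            f"window of {window_s} s is shorter than the minimum admissible "
            f"duration {min_duration_s(band):.2f} s"
        )
    samples_per = int(round(window_s * signal.fs))
    out: list[tuple[float, RrEstimate]] = []
    for w in range(num_windows(signal.duration, window_s)):
        chunk = signal.samples[w * samples_per : (w + 1) * samples_per]
        rec = SignalRecord(chunk, signal.fs, signal.label)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out.append((w * window_s, estimate_rr(rec, config, band, edge_trim_s)))
    return out
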