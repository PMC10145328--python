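"""Wavelet-based reference respiratory rate from a respiration channel.

The ground-truth RR for validation comes straight from the respiration belt
signal: a complex-Morlet scalogram restricted to the respiration band, its
time-averaged spectrum, and the band-limited argmax converted to bpm.  The
frequency grid is uniform at 0.01 Hz (0.6 bpm granularity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .rr import RrBand, min_duration_s
from .signal import SignalRecord

__all__ = ["Scalogram", "RefRr", "morlet_scalogram", "time_averaged_spectrum", "rr_from_spectrum", "reference_rr"]

DEFAULT_WAVELET = "cmor1.0-1.0"  # complex Morlet, bandwidth 1.0, centre frequency 1.0


@dataclass(frozen=True)
class Scalogram:
    """Squared-magnitude CWT surface over time x frequency."""

    energy: np.ndarray  # (N, F), nonnegative
    freqs: np.ndarray  # Hz, uniform grid
    fs: float
    wavelet: str

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0]) if self.freqs.size > 1 else 0.0


@dataclass(frozen=True)
class RefRr:
    """Reference RR with its supporting time-averaged spectrum."""

    rr_bpm: float
    peak_freq: float  # Hz
    spectrum: np.ndarray  # over the freq grid
    freqs: np.ndarray
    low_confidence: bool = False  # flat spectrum — argmax not informative


def _band_grid(band: RrBand, df: float) -> np.ndarray:
    n_bins = int(round((band.upper_hz - band.lower_hz) / df)) + 1
    return band.lower_hz + df * np.arange(n_bins)


def morlet_scalogram(
    signal: SignalRecord,
    band: RrBand | None = None,
    df: float = 0.01,
    wavelet: str = DEFAULT_WAVELET,
) -> Scalogram:
    """Complex-Morlet scalogram on a uniform frequency grid over the band.

    Scales are chosen so each CWT row maps exactly onto one grid frequency
    (``scale = f_c * fs / f``).  Each row's squared magnitude is divided by
    its scale (power normalization): with the amplitude normalization of the
    raw transform a pure tone's ridge peaks a few percent below its true
    frequency, whereas the power-normalized ridge peaks at the tone frequency
    exactly on the grid.  The record must cover at least one cycle at the
    band's lower edge.
    """
    band = band if band is not None else RrBand()
    if df <= 0:
        raise ValueError(f"df must be positive, got {df}")
    if signal.duration < min_duration_s(band):
        raise ValueError(
            f"record of {signal.duration:.2f} s too short for the "
            f"{band.lower_hz}-{band.upper_hz} Hz band"
        )
    freqs = _band_grid(band, df)
    if freqs[-1] >= signal.fs / 2:
        raise ValueError("band extends beyond the Nyquist frequency")
    fc = pywt.central_frequency(wavelet)
    scales = fc * signal.fs / freqs
    coef, actual = pywt.cwt(
        signal.samples, scales, wavelet, sampling_period=1.0 / signal.fs, method="fft"
    )
    np.testing.assert_allclose(actual, freqs, rtol=1e-9)
    energy = (np.abs(coef) ** 2 / scales[:, None]).T  # power-normalized, time x freq
    return Scalogram(energy=energy, freqs=freqs, fs=signal.fs, wavelet=wavelet)


def time_averaged_spectrum(sc: Scalogram) -> np.ndarray:
    """Plain time mean of the scalogram at each grid frequency."""
    if sc.energy.size == 0:
        raise ValueError("empty scalogram")
    return sc.energy.mean(axis=0)


def rr_from_spectrum(spectrum: np.ndarray, freqs: np.ndarray, band: RrBand | None = None) -> RefRr:
    """Band-limited argmax of the time-averaged spectrum, in bpm.

    Ties (and an entirely flat spectrum) resolve to the lowest frequency; the
    flat case is flagged low-confidence.
    """
    band = band if band is not None else RrBand()
    s = np.asarray(spectrum, dtype=np.float64)
    f = np.asarray(freqs, dtype=np.float64)
    mask = (f >= band.lower_hz) & (f <= band.upper_hz)
    if not mask.any():
        raise ValueError("frequency grid does not cover the requested band")
    s_band, f_band = s[mask], f[mask]
    i = int(np.argmax(s_band))  # first occurrence = lowest frequency on ties
    flat = bool(np.all(s_band == s_band[0]))
    return RefRr(
        rr_bpm=60.0 * float(f_band[i]),
        peak_freq=float(f_band[i]),
        spectrum=s,
        freqs=f,
        low_confidence=flat,
    )


def reference_rr(
    signal: SignalRecord,
    band: RrBand | None = None,
    df: float = 0.01,
    wavelet: str = DEFAULT_WAVELET,
) -> RefRr:
    """Convenience pipeline: scalogram -> time average -> band argmax."""
    sc = morlet_scalogram(signal, band, df, wavelet)
    return rr_from_spectrum(time_averaged_spectrum(sc), sc.freqs, band)
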