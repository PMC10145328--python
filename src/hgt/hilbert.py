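"""Hilbert spectral analysis of decomposed IMFs.

Each IMF x_i is lifted to its analytic signal z_i = x_i + j H{x_i} whose
modulus a_i is the instantaneous amplitude and whose unwrapped phase gradient,
scaled by fs / 2*pi, is the instantaneous frequency in Hz.  Depositing each
sample's energy a_i^2[n] at its instantaneous frequency and summing over IMFs
yields the Hilbert spectrum H(n, f).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

__all__ = [
    "AnalyticImf",
    "HilbertSpectrum",
    "analytic_signal",
    "instantaneous_frequency",
    "hilbert_spectrum",
]


@dataclass(frozen=True)
class AnalyticImf:
    """Analytic-signal view of one IMF: amplitude, phase and frequency tracks."""

    index: int
    amplitude: np.ndarray
    phase: np.ndarray  # unwrapped, radians
    inst_freq: np.ndarray  # Hz
    fs: float
    phase_degenerate: bool = field(default=False)

    @property
    def n(self) -> int:
        return int(self.amplitude.size)


def analytic_signal(imf: np.ndarray, fs: float, index: int = 1) -> AnalyticImf:
    """Analytic signal of an IMF via the frequency-domain construction.

    Negative DFT frequencies are zeroed and positive ones doubled (with the
    conventional half-weight at DC and, for even length, at Nyquist), which is
    the discrete Hilbert transformer.  Amplitude is ``sqrt(x**2 + y**2)``;
    phase is the unwrapped ``atan2(y, x)``; instantaneous frequency follows
    from the phase gradient.

    A constant input has no meaningful phase: amplitude is ``|c|``, phase is
    set to zero and the result is flagged ``phase_degenerate`` with a warning.
    """
    x = np.asarray(imf, dtype=np.float64)
    if x.size < 8:
        raise ValueError(f"IMF too short for analytic-signal analysis: {x.size} < 8")
    if not np.all(np.isfinite(x)):
        raise ValueError("IMF contains non-finite samples")

    if np.ptp(x) == 0.0:
        warnings.warn(
            "constant IMF: phase undefined, set to zero", RuntimeWarning, stacklevel=2
        )
        amp = np.full(x.size, abs(float(x[0])))
        phase = np.zeros(x.size)
        freq = np.zeros(x.size)
        return AnalyticImf(index, amp, phase, freq, float(fs), phase_degenerate=True)

    z = scipy.signal.hilbert(x)
    amp = np.abs(z)
    phase = np.unwrap(np.angle(z))
    freq = instantaneous_frequency(phase, fs)
    return AnalyticImf(index, amp, phase, freq, float(fs))


def instantaneous_frequency(phase: np.ndarray, fs: float) -> np.ndarray:
    """Instantaneous frequency in Hz from an unwrapped phase track.

    The per-sample angular increment is the discrete gradient of the phase
    (central differences in the interior, one-sided at the ends); conversion
    to Hz multiplies by ``fs / (2 pi)``.
    """
    theta = np.asarray(phase, dtype=np.float64)
    if theta.size < 2:
        raise ValueError(f"need at least 2 phase samples, got {theta.size}")
    omega = np.gradient(theta)  # radians per sample
    return omega * (fs / (2.0 * np.pi))


@dataclass(frozen=True)
class HilbertSpectrum:
    """Time-frequency energy surface summed over IMF layers.

    ``grid`` is time x frequency; each IMF contributes at most one nonzero
    bin per time sample (the bin containing its instantaneous frequency).
    Samples whose frequency falls outside the grid are accumulated in
    ``overflow`` rather than silently dropped, so total mass is conserved:
    ``grid.sum() + overflow == sum_i sum_n weight_i[n]``.
    """

    time: np.ndarray  # seconds, length N
    freq_edges: np.ndarray  # Hz, length F+1, uniform
    grid: np.ndarray  # (N, F) summed over IMFs
    bin_index: np.ndarray  # (P, N) int, -1 = overflow
    weights: np.ndarray  # (P, N) deposited mass per sample
    overflow: float
    imf_indices: tuple[int, ...]
    weighting: str  # "energy" (a^2) or "amplitude" (a)

    @property
    def freq_centers(self) -> np.ndarray:
        return 0.5 * (self.freq_edges[:-1] + self.freq_edges[1:])

    def layer(self, i: int) -> np.ndarray:
        """Dense (N, F) contribution of the i-th IMF in the input list."""
        n, f = self.grid.shape
        out = np.zeros((n, f))
        idx = self.bin_index[i]
        ok = idx >= 0
        out[np.flatnonzero(ok), idx[ok]] = self.weights[i, ok]
        return out

    def total_mass(self) -> float:
        return float(self.grid.sum() + self.overflow)


def hilbert_spectrum(
    imfs: list[AnalyticImf],
    fs: float | None = None,
    df: float = 0.01,
    f_max: float | None = None,
    weighting: str = "energy",
) -> HilbertSpectrum:
    """Assemble the Hilbert spectrum from analytic IMFs.

    Each sample n of IMF i deposits ``a_i[n]**2`` (or ``a_i[n]`` with
    amplitude weighting) into the frequency bin containing ``f_i[n]``; the
    per-IMF layers are summed.  Frequencies outside ``[0, f_max)`` — e.g.
    negative instantaneous frequencies near boundaries — go to the overflow
    bucket.

    Parameters
    ----------
    imfs
        Analytic IMFs of equal length and sampling frequency.
    fs
        Sampling frequency; defaults to the IMFs' own.
    df
        Frequency bin width in Hz (default 0.01).
    f_max
        Upper edge of the grid; defaults to the Nyquist frequency.  Choose a
        band of interest (e.g. 0.5 Hz for respiration) to keep the grid small.
    weighting
        ``"energy"`` (default) or ``"amplitude"``.
    """
    if not imfs:
        raise ValueError("need at least one analytic IMF")
    if weighting not in ("energy", "amplitude"):
        raise ValueError(f"weighting must be 'energy' or 'amplitude', got {weighting!r}")
    if df <= 0:
        raise ValueError(f"df must be positive, got {df}")
    fs = float(imfs[0].fs if fs is None else fs)
    n = imfs[0].n
    if any(a.n != n for a in imfs):
        raise ValueError("all IMFs must share the same length")

    if f_max is None:
        f_max = fs / 2.0
    n_bins = int(np.ceil(f_max / df))
    edges = df * np.arange(n_bins + 1)

    p = len(imfs)
    bin_index = np.full((p, n), -1, dtype=np.int64)
    weights = np.zeros((p, n))
    grid = np.zeros((n, n_bins))
    overflow = 0.0
    for i, a in enumerate(imfs):
        w = a.amplitude**2 if weighting == "energy" else a.amplitude
        idx = np.floor(a.inst_freq / df).astype(np.int64)
        ok = (a.inst_freq >= 0.0) & (idx >= 0) & (idx < n_bins)
        bin_index[i, ok] = idx[ok]
        weights[i] = w
        overflow += float(w[~ok].sum())
        rows = np.flatnonzero(ok)
        np.add.at(grid, (rows, idx[ok]), w[ok])

    return HilbertSpectrum(
        time=np.arange(n) / fs,
        freq_edges=edges,
        grid=grid,
        bin_index=bin_index,
        weights=weights,
        overflow=overflow,
        imf_indices=tuple(a.index for a in imfs),
        weighting=weighting,
    )
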