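"""Gaussian average filtering decomposition (GAFD).

GAFD peels intrinsic mode functions (IMFs) off a signal one at a time.  Each
sifting round smooths the current working signal with a normalized Gaussian
moving average whose half-length adapts to the number of local extrema; the
difference between the working signal and its smoothed instantaneous mean is
emitted as the next IMF, and the smoothed mean becomes the working signal of
the following round.  Because Gaussian smoothing is a low-pass operation, the
IMFs come out ordered from high to low frequency and the final working signal
is the residual trend.  The identity

    s[n] = sum_k imf_k[n] + residual[n]

holds exactly by construction (telescoping sum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .signal import SignalRecord

__all__ = [
    "ExtensionStyle",
    "GaussianWindow",
    "GafdConfig",
    "SiftRound",
    "Decomposition",
    "build_gaussian_window",
    "count_local_extrema",
    "window_half_length",
    "extend_signal",
    "instantaneous_mean",
    "gafd",
]

# Minimum admissible Gaussian shape parameter: endpoint taps of the window stay
# below 5% of the centre tap, so the discrete window still behaves like a
# Gaussian (its spectrum remains near-Gaussian, i.e. monotone low-pass).
ALPHA_MIN = 2.45

# Default shape parameter: endpoint taps are ~0.025% of the centre tap.
ALPHA_DEFAULT = 4.0728


class ExtensionStyle(str, Enum):
    """Boundary-extension conventions applied before the moving average."""

    CONSTANT = "constant"
    PERIODICAL = "periodical"
    REFLECTION = "reflection"
    DOUBLE_SYMMETRIC_REFLECTION = "double_symmetric_reflection"


@dataclass(frozen=True)
class GaussianWindow:
    """A normalized (2M+1)-tap Gaussian smoothing kernel."""

    alpha: float
    half_length: int
    coeffs: np.ndarray

    @property
    def length(self) -> int:
        return 2 * self.half_length + 1


def build_gaussian_window(half_length: int, alpha: float = ALPHA_DEFAULT) -> GaussianWindow:
    """Build the normalized discrete Gaussian window.

    The unnormalized taps are ``w[m] = exp(-((alpha * m / M)**2) / 2)`` for
    ``-M <= m <= M``; they are divided by their sum so the kernel has unit DC
    gain and the moving average preserves signal energy at low frequency.

    Parameters
    ----------
    half_length
        M; the kernel has ``2 M + 1`` taps.
    alpha
        Shape parameter, inversely proportional to the standard deviation of
        the underlying Gaussian.  Larger alpha concentrates the window.
    """
    if half_length < 1:
        raise ValueError(f"half_length must be >= 1, got {half_length}")
    if not alpha > 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    m = np.arange(-half_length, half_length + 1, dtype=np.float64)
    w = np.exp(-0.5 * (alpha * m / half_length) ** 2)
    return GaussianWindow(float(alpha), int(half_length), w / w.sum())


def count_local_extrema(signal: np.ndarray) -> int:
    """Count strict interior local extrema via the first-difference sign test.

    Sample ``n`` is an extremum iff ``(s[n]-s[n-1]) * (s[n+1]-s[n]) < 0``.
    Runs of equal samples (plateaus) are collapsed: a sign change across a
    plateau counts as a single extremum.  Endpoints are never counted.
    Sequences shorter than 3 samples have no interior and return 0.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.size < 3:
        return 0
    d = np.diff(x)
    nz = np.flatnonzero(d)
    if nz.size < 2:
        return 0
    s = np.sign(d[nz])
    return int(np.count_nonzero(s[:-1] * s[1:] < 0))


def window_half_length(n: int, n_extrema: int, epsilon: float) -> int | None:
    """Adaptive window half-length ``M = 2 * floor(epsilon * N / Ne)``.

    Returns ``None`` (terminate sifting) when no extrema remain, when the
    computed M collapses below 1, or when the window would no longer fit the
    signal (``M >= N/2 - 1``).
    """
    if n < 3:
        raise ValueError(f"signal length must be >= 3, got {n}")
    if n_extrema <= 0:
        return None
    m = 2 * math.floor(epsilon * n / n_extrema)
    if m < 1 or m >= n / 2 - 1:
        return None
    return m


def extend_signal(signal: np.ndarray, half_length: int, style: ExtensionStyle | str) -> np.ndarray:
    """Extend a signal by M samples on each side before filtering.

    Styles:

    - ``constant``: hold the boundary value.
    - ``periodical``: circular wrap.
    - ``reflection``: whole-point mirror about the boundary sample
      (``s_e[-k] = s[k]``), the boundary sample itself not repeated.
    - ``double_symmetric_reflection``: half-point mirror about the record
      edge (``s_e[-k] = s[k-1]``), so the boundary sample appears on both
      sides of the fold.  This is the package default: a mirror-type
      extension continues local oscillations without injecting a spurious
      trend, which keeps the smoothed mean a genuine low-pass estimate right
      up to the record ends.  (A point reflection ``s_e[-k] = 2 s[0] - s[k]``
      was rejected: by antisymmetry it forces the moving average to
      interpolate the raw boundary sample exactly — unit gain at every
      frequency at the edge — so each IMF would carry a forced zero there,
      maximising rather than suppressing the boundary effect.)
    """
    x = np.asarray(signal, dtype=np.float64)
    n, m = x.size, int(half_length)
    style = ExtensionStyle(style)
    if m < 1:
        raise ValueError(f"half_length must be >= 1, got {m}")
    if style is ExtensionStyle.REFLECTION and m >= n:
        raise ValueError(f"reflection extension needs M < N, got M={m}, N={n}")
    if style is ExtensionStyle.DOUBLE_SYMMETRIC_REFLECTION and m > n:
        raise ValueError(f"double-symmetric extension needs M <= N, got M={m}, N={n}")
    if style is ExtensionStyle.CONSTANT:
        left = np.full(m, x[0])
        right = np.full(m, x[-1])
    elif style is ExtensionStyle.PERIODICAL:
        reps = -(-m // n)  # ceil, in case M > N
        left = np.tile(x, reps)[-m:]
        right = np.tile(x, reps)[:m]
    elif style is ExtensionStyle.REFLECTION:
        left = x[m:0:-1]
        right = x[-2 : -m - 2 : -1]
    else:  # double symmetric reflection (half-point mirror)
        left = x[:m][::-1]
        right = x[n - m :][::-1]
    return np.concatenate([left, x, right])


def instantaneous_mean(extended: np.ndarray, window: GaussianWindow) -> np.ndarray:
    """Gaussian moving average over the valid region of an extended signal.

    ``extended`` must have length ``N + 2M``; the result has length N and
    equals the convolution of the extended signal with the (symmetric) kernel
    restricted to the original support.
    """
    xe = np.asarray(extended, dtype=np.float64)
    m = window.half_length
    n = xe.size - 2 * m
    if n < 1:
        raise ValueError(
            f"extended length {xe.size} incompatible with window half-length {m}"
        )
    # symmetric kernel: correlation == convolution
    out = np.convolve(xe, window.coeffs, mode="valid")
    assert out.size == n
    return out


@dataclass(frozen=True)
class GafdConfig:
    """Tunable parameters of the sifting loop.

    ``alpha`` shapes the Gaussian kernel (>= 2.45 so the window keeps its
    Gaussian character); ``epsilon`` in [1.1, 3] scales the adaptive window
    length relative to the mean extrema spacing.  The two energy thresholds
    terminate sifting when the residual has become negligible
    (``energy_ratio_threshold``, original-to-residual energy ratio) or when
    successive IMFs no longer differ in energy (``energy_diff_threshold``,
    relative to the original signal energy).  ``max_imfs`` is a hard safeguard.
    """

    alpha: float = ALPHA_DEFAULT
    epsilon: float = 1.8
    extension_style: ExtensionStyle = ExtensionStyle.DOUBLE_SYMMETRIC_REFLECTION
    energy_ratio_threshold: float = 1e6
    energy_diff_threshold: float = 1e-3
    max_imfs: int = 12

    def __post_init__(self) -> None:
        if not 1.1 <= self.epsilon <= 3.0:
            raise ValueError(f"epsilon must lie in [1.1, 3], got {self.epsilon}")
        if self.alpha < ALPHA_MIN:
            raise ValueError(f"alpha must be >= {ALPHA_MIN}, got {self.alpha}")
        if self.energy_ratio_threshold <= 0 or self.energy_diff_threshold <= 0:
            raise ValueError("energy thresholds must be positive")
        if self.max_imfs < 1:
            raise ValueError(f"max_imfs must be >= 1, got {self.max_imfs}")
        object.__setattr__(self, "extension_style", ExtensionStyle(self.extension_style))


@dataclass(frozen=True)
class SiftRound:
    """Diagnostics of one sifting round."""

    index: int  # 1-based IMF index this round emitted (or tried to)
    n_extrema: int
    half_length: int | None
    stop_reason: str | None  # None while sifting continues


@dataclass(frozen=True)
class Decomposition:
    """Ordered IMFs plus residual; ``sum(imfs) + residual == input`` exactly."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    rounds: list[SiftRound] = field(default_factory=list)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    @property
    def windows(self) -> list[int]:
        """Per-round Gaussian half-lengths M (rounds that emitted an IMF)."""
        return [r.half_length for r in self.rounds if r.half_length is not None]

    @property
    def stop_reason(self) -> str:
        return self.rounds[-1].stop_reason if self.rounds else "no_rounds"

    def reconstruction(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


def gafd(signal: SignalRecord, config: GafdConfig | None = None) -> Decomposition:
    """Decompose a signal into IMFs by Gaussian moving-average sifting.

    Each round: count the local extrema of the working signal, derive the
    adaptive half-length M, extend the boundaries, smooth with the normalized
    Gaussian window, emit ``IMF = working - mean`` and continue on the
    smoothed mean.  Termination: the window-length bound, the
    original-to-residual energy-ratio threshold, the neighbouring-IMF
    energy-difference threshold, or the ``max_imfs`` safeguard — whichever
    fires first.  The per-round diagnostics record which one it was.
    """
    cfg = config if config is not None else GafdConfig()
    s = signal.samples
    n = s.size
    if n < 3:
        raise ValueError(f"need at least 3 samples to decompose, got {n}")

    e_orig = float(np.sum(s * s))
    working = s.copy()
    imfs: list[np.ndarray] = []
    rounds: list[SiftRound] = []
    prev_imf_energy: float | None = None

    while True:
        k = len(imfs) + 1
        ne = count_local_extrema(working)
        m = window_half_length(n, ne, cfg.epsilon)
        if m is None:
            rounds.append(SiftRound(k, ne, None, "window_bound"))
            break

        win = build_gaussian_window(m, cfg.alpha)
        ext = extend_signal(working, m, cfg.extension_style)
        mean = instantaneous_mean(ext, win)
        imf = working - mean
        imfs.append(imf)
        working = mean

        stop: str | None = None
        e_res = float(np.sum(working * working))
        e_imf = float(np.sum(imf * imf))
        if e_orig > 0 and (e_res == 0.0 or e_orig / e_res > cfg.energy_ratio_threshold):
            stop = "energy_ratio"
        elif (
            prev_imf_energy is not None
            and e_orig > 0
            and abs(e_imf - prev_imf_energy) / e_orig < cfg.energy_diff_threshold
        ):
            stop = "energy_diff"
        elif len(imfs) >= cfg.max_imfs:
            stop = "max_imfs"
        prev_imf_energy = e_imf
        rounds.append(SiftRound(k, ne, m, stop))
        if stop is not None:
            break

    return Decomposition(imfs=imfs, residual=working, rounds=rounds)
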