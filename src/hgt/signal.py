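"""Uniformly sampled single-channel signals.

:class:`SignalRecord` is the universal input type of the package: a real-valued
sequence together with its sampling frequency.  Physiological sources (finger
PPG, wrist PPG, SCG, respiration belt) all arrive in this form after resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SignalRecord"]


@dataclass(frozen=True)
class SignalRecord:
    """A uniformly sampled real-valued time series.

    Parameters
    ----------
    samples
        Signal values in arbitrary units.  Converted to a float64 array.
    fs
        Sampling frequency in Hz.  Must be positive.
    label
        Free-text description of the source (e.g. ``"finger_ppg"``).
    """

    samples: np.ndarray
    fs: float
    label: str = field(default="")

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=np.float64)
        if x.ndim != 1:
            raise ValueError(f"samples must be one-dimensional, got shape {x.shape}")
        if x.size < 2:
            raise ValueError(f"need at least 2 samples, got {x.size}")
        if not np.all(np.isfinite(x)):
            bad = int(np.flatnonzero(~np.isfinite(x))[0])
            raise ValueError(f"non-finite sample at index {bad}")
        if not (self.fs > 0 and np.isfinite(self.fs)):
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        object.__setattr__(self, "samples", x)
        object.__setattr__(self, "fs", float(self.fs))

    @property
    def n(self) -> int:
        """Number of samples."""
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record duration in seconds (``n / fs``)."""
        return self.n / self.fs

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds, starting at zero."""
        return np.arange(self.n) / self.fs

    def with_samples(self, samples: np.ndarray, fs: float | None = None) -> "SignalRecord":
        """Return a copy carrying new samples (and optionally a new fs)."""
        return SignalRecord(samples, self.fs if fs is None else fs, self.label)
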