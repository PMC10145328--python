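"""Readers, writers and resampling for signal records."""

from __future__ import annotations

import json
import warnings
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal

from .decompose import Decomposition, GafdConfig
from .signal import SignalRecord

__all__ = ["read_record", "write_record", "resample_to", "write_decomposition"]

# Relative tolerance on time-step uniformity when inferring fs from a time column.
_STEP_RTOL = 0.01


def read_record(path: str | Path, fs: float | None = None, label: str = "") -> SignalRecord:
    """Read a signal from CSV.

    Two-column files are interpreted as ``time_s, value`` and the sampling
    frequency is inferred from the (required uniform) time steps; one-column
    files need an explicit ``fs``.  A header row is tolerated.  Non-finite
    samples are rejected with the offending row reported.
    """
    path = Path(path)
    df = pd.read_csv(path, header=None, comment="#")
    # tolerate a header row: drop it if the first row fails float conversion
    try:
        df.iloc[0].astype(float)
    except (ValueError, TypeError):
        df = df.iloc[1:].reset_index(drop=True)
    df = df.astype(float)

    if df.shape[1] == 1:
        if fs is None:
            raise ValueError(f"{path}: one-column CSV requires an explicit sampling frequency")
        values = df.iloc[:, 0].to_numpy()
    elif df.shape[1] == 2:
        t = df.iloc[:, 0].to_numpy()
        values = df.iloc[:, 1].to_numpy()
        steps = np.diff(t)
        if steps.size == 0 or np.any(steps <= 0):
            raise ValueError(f"{path}: time column must be strictly increasing")
        step = float(np.median(steps))
        if np.max(np.abs(steps - step)) > _STEP_RTOL * step:
            raise ValueError(
                f"{path}: nonuniform sampling (time steps deviate more than "
                f"{_STEP_RTOL:.0%} from {step:g} s)"
            )
        inferred = 1.0 / step
        if fs is not None and abs(fs - inferred) > _STEP_RTOL * inferred:
            raise ValueError(
                f"{path}: declared fs {fs} Hz contradicts time column ({inferred:g} Hz)"
            )
        fs = inferred
    else:
        raise ValueError(f"{path}: expected 1 or 2 columns, found {df.shape[1]}")

    if not np.all(np.isfinite(values)):
        bad = int(np.flatnonzero(~np.isfinite(values))[0])
        raise ValueError(f"{path}: non-finite sample at data row {bad}")
    return SignalRecord(values, fs, label or path.stem)


def write_record(signal: SignalRecord, path: str | Path) -> None:
    """Write ``time_s,value`` CSV at full float precision (lossless round-trip)."""
    df = pd.DataFrame({"time_s": signal.time, "value": signal.samples})
    df.to_csv(path, index=False, float_format="%.17g")


def resample_to(signal: SignalRecord, fs_target: float) -> SignalRecord:
    """Rational-factor polyphase resampling with anti-aliasing.

    Duration is preserved to within one output sample.  Identity when the
    target equals the current rate.  Upsampling beyond 10x draws a warning.
    """
    if fs_target <= 0:
        raise ValueError(f"target sampling frequency must be positive, got {fs_target}")
    if fs_target == signal.fs:
        return signal
    frac = Fraction(fs_target / signal.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    if up / down > 10:
        warnings.warn(
            f"upsampling by {up / down:.1f}x exceeds 10x; interpolation error may grow",
            RuntimeWarning,
            stacklevel=2,
        )
    y = scipy.signal.resample_poly(signal.samples, up, down)
    return SignalRecord(y, fs_target, signal.label)


def write_decomposition(
    dec: Decomposition,
    signal: SignalRecord,
    path: str | Path,
    config: GafdConfig | None = None,
) -> None:
    """Write IMFs + residual as CSV with a JSON sidecar of per-round diagnostics."""
    path = Path(path)
    cols = {f"imf_{k + 1}": imf for k, imf in enumerate(dec.imfs)}
    cols["residual"] = dec.residual
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    cfg = config if config is not None else GafdConfig()
    sidecar = {
        "fs": signal.fs,
        "label": signal.label,
        "n_imfs": dec.n_imfs,
        "rounds": [
            {
                "index": r.index,
                "n_extrema": r.n_extrema,
                "half_length": r.half_length,
                "stop_reason": r.stop_reason,
            }
            for r in dec.rounds
        ],
        "config": {
            "alpha": cfg.alpha,
            "epsilon": cfg.epsilon,
            "extension_style": cfg.extension_style.value,
            "energy_ratio_threshold": cfg.energy_ratio_threshold,
            "energy_diff_threshold": cfg.energy_diff_threshold,
            "max_imfs": cfg.max_imfs,
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
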