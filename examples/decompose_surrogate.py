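"""Decompose a respiration-modulated cardiac surrogate into IMFs.

Builds a 60-s signal whose 1.2 Hz cardiac oscillation is amplitude- and
baseline-modulated by 12-bpm breathing, runs the Gaussian average filtering
decomposition, and prints what each sifting round did and where each IMF's
spectral energy sits.
"""

import numpy as np
from scipy.signal import periodogram

from hgt import SynthSpec, gafd, make_ppg_surrogate

rec, truth = make_ppg_surrogate(SynthSpec(rr_bpm=12.0))
dec = gafd(rec)

print(f"input: {rec.duration:.0f} s at {rec.fs:.0f} Hz, true RR {truth[0][1]:.0f} bpm")
print(f"{dec.n_imfs} IMFs, final stop reason: {dec.stop_reason}\n")
print("round  extrema  half-length  stop")
for r in dec.rounds:
    print(f"{r.index:>5}  {r.n_extrema:>7}  {r.half_length!s:>11}  {r.stop_reason or '-'}")

print("\nIMF  energy   periodogram peak (Hz)")
for k, imf in enumerate(dec.imfs):
    f, p = periodogram(imf, fs=rec.fs)
    print(f"{k + 1:>3}  {np.sum(imf**2):>7.1f}  {f[np.argmax(p)]:.3f}")

err = np.max(np.abs(rec.samples - dec.reconstruction()))
print(f"\nreconstruction error: {err:.2e} (IMFs + residual rebuild the input exactly)")
# The highest-frequency IMF carries the cardiac band (~1.2 Hz); a later IMF
# carries the 0.2 Hz respiratory oscillation the estimator will select.
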