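# hgt — respiratory rate from PPG and SCG by Gaussian average filtering decomposition

Respiration leaves its imprint on pulse and chest-acceleration signals: the
amplitude and baseline of a finger/wrist photoplethysmogram (PPG) or a
seismocardiogram (SCG) oscillate slowly at the breathing frequency.  `hgt`
extracts that component and turns it into a respiratory-rate (RR) estimate,
for researchers working on contactless or wearable vital-sign monitoring who
need a decomposition-based estimator plus the validation statistics to judge
it.

## Method

1. **Gaussian average filtering decomposition (GAFD).**  The signal *s[n]* is
   sifted into intrinsic mode functions: each round smooths the working
   signal with a normalized Gaussian window
   *w<sub>G</sub>[m] ∝ exp(−(α·m/M)²/2)*, |m| ≤ M, whose half-length adapts
   to the extrema count, *M = 2⌊ε·N/N<sub>e</sub>⌋* (defaults α = 4.0728,
   ε = 1.8).  The difference between the working signal and its smoothed
   instantaneous mean is emitted as the next IMF and sifting continues on the
   mean, so IMFs come out ordered high → low frequency and
   Σ<sub>k</sub> IMF<sub>k</sub> + residual ≡ *s* exactly.  Sifting stops on a
   window-length bound (M ≥ N/2 − 1), an energy-ratio or energy-difference
   criterion, or a hard IMF cap.
2. **Hilbert spectral analysis.**  Each IMF *x<sub>i</sub>* becomes the
   analytic signal *z<sub>i</sub> = x<sub>i</sub> + jH{x<sub>i</sub>} =
   a<sub>i</sub>e<sup>jθ<sub>i</sub></sup>*; the instantaneous frequency is
   *f<sub>i</sub>[n] = (f<sub>s</sub>/2π)·dθ<sub>i</sub>/dn*.  Binning
   *a<sub>i</sub>²[n]* at *f<sub>i</sub>[n]* and summing layers gives the
   Hilbert spectrum *H(n, f)*.
3. **Candidate screening and selection.**  IMFs whose mean IF lies in the
   respiration band [0.09, 0.35] Hz (5.4–21 bpm) are candidates; with several
   candidates the one with the smallest IF standard deviation wins, and
   **RR = 60 · f̄<sub>i</sub>** bpm.  Records must span at least one cycle at
   the band's lower edge (11.11 s; ≥ 20 s recommended).
4. **Validation tooling.**  A complex-Morlet scalogram reference estimator
   for the respiration channel (0.01-Hz grid, band-limited argmax), ICC(A,1)
   with its F-based confidence interval, and Bland–Altman limits of agreement
   (bias ± 1.96·SD of paired differences).

## Worked example

```python
from hgt import SynthSpec, estimate_rr, make_ppg_surrogate

rec, truth = make_ppg_surrogate(SynthSpec(rr_bpm=12.0))  # 60 s at 100 Hz
est = estimate_rr(rec)
print(f"{est.rr_bpm:.2f} bpm via IMF {est.selected_imf}")
```

prints

```
11.94 bpm via IMF 3
```

— the 1.2 Hz cardiac oscillation lands in IMF 1, the 0.2 Hz respiratory
component in IMF 3 (mean IF 0.199 Hz, IF std 0.041, the tightest in-band
track), and 60 × 0.199 = 11.94 bpm against a ground truth of 12.  The
`examples/` directory has one narrative script per capability
(decomposition, RR estimation and paced-change tracking, Hilbert spectrum,
wavelet reference, agreement statistics, noise robustness); each prints its
numbers with a note on what they mean.  The same functionality is reachable
from the shell through the thin `hgt` CLI (`hgt synth`, `hgt decompose`,
`hgt rr`, `hgt refrr`, `hgt spectrum`, `hgt agree`).

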