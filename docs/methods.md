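# Methods

## Model and assumptions

The estimator assumes a single-channel, uniformly sampled signal in which a
fast quasi-periodic oscillation (cardiac, ~1–2 Hz) is amplitude- and
baseline-modulated by respiration, and that the respiration frequency lies in
a known physiologic band.  Nothing is assumed about waveform shape: the
decomposition is fully data-adaptive, which is what makes one pipeline serve
finger PPG, wrist PPG and SCG alike.

### Sifting loop

Each round of Gaussian average filtering decomposition (GAFD):

1. counts the local extrema N<sub>e</sub> of the current working signal
   (first-difference sign-change test; plateaus collapse to one extremum);
2. sets the window half-length M = 2⌊ε·N/N<sub>e</sub>⌋ and terminates if
   M < 1 or M ≥ N/2 − 1 (window no longer fits) or N<sub>e</sub> = 0;
3. extends the signal by M samples per side, smooths with the normalized
   (2M+1)-tap Gaussian window, emits IMF = working − mean, and recurses on
   the **mean**.

Recursing on the smoothed mean (rather than the emitted detail) yields the
detail-first ordering standard for EMD-family methods: the residual grows
smoother every round, which is also the reading under which the adaptive
window formula is meaningful — the extrema count of the operand must fall as
sifting proceeds.

Stopping: besides the window bound, sifting ends when the ratio of original
to residual energy exceeds `energy_ratio_threshold` (default 1e6 — the
residual carries less than a millionth of the input energy) or when two
consecutive IMFs differ in energy by less than `energy_diff_threshold`
(default 1e-3) of the input energy, or at `max_imfs` (default 12, a
safeguard against pathological inputs).  The two energy thresholds have no
canonical published values; both are configurable and echoed into the JSON
sidecar of every decomposition.

### Boundary extension

Four extension styles are provided: `constant` (hold), `periodical` (wrap),
`reflection` (whole-point mirror, s<sub>e</sub>[−k] = s[k]) and the default
`double_symmetric_reflection` (half-point mirror, s<sub>e</sub>[−k] = s[k−1],
the boundary sample appearing on both sides of the fold).

The choice of a mirror-type convention for the default was a genuinely open
design point and deserves its rationale: the alternative point reflection
s<sub>e</sub>[−k] = 2s[0] − s[k] looks attractive because it preserves slope
continuity, but by antisymmetry it forces the Gaussian moving average to
reproduce the boundary sample exactly (m[0] = s[0] — unit gain at **every**
frequency at the edge).  Every IMF then carries a forced zero at the record
ends, the instantaneous-frequency track collapses there, and on the
synthetic protocol below the RR error grows to ~1.5 bpm MAE with unstable
candidate selection.  The half-point mirror keeps the smoother a genuine
low-pass estimate up to the edge (grid MAE ~0.05 bpm, noiseless and 5 dB
alike), so it is the default.

### Hilbert analysis and selection rule

The analytic signal uses the standard frequency-domain construction
(negative DFT bins zeroed, positive doubled, half-weight at DC/Nyquist).
Instantaneous frequency is the gradient of the unwrapped phase — central
differences in the interior, one-sided at the ends — scaled by f<sub>s</sub>/2π.
Constant IMFs have no phase; they are flagged and given zero phase.

The per-IMF mean and (N−1)-denominator standard deviation of the IF are
computed over **all** samples, boundary included; no trimming is applied, so
short windows inherit some edge bias (see Limitations).  Candidates are IMFs
with mean IF inside the inclusive band [0.09, 0.35] Hz; the minimum-std rule
resolves multiplicity, with ties broken deterministically toward the lower
IMF index.  Negative IF samples (possible near edges) stay in the statistics
but are diverted to an overflow bucket when binning the Hilbert spectrum, so
spectral mass is conserved exactly: Σ grid + overflow = Σ<sub>i,n</sub> a<sub>i</sub>²[n].

### Wavelet reference

The reference RR comes from the respiration channel: complex-Morlet
(`cmor1.0-1.0`, both shape parameters 1.0 in normalized units, configurable)
continuous wavelet transform with scales mapped one-to-one onto a uniform
0.01-Hz grid over the band, squared magnitude **divided by the scale** per
row, time-averaged, band-limited argmax, RR = 60·f<sub>peak</sub>.  The
per-scale power normalization matters: under the transform's raw amplitude
normalization a stationary tone's time-averaged ridge peaks ≈ 2.5% below the
tone frequency (the √scale factor shifts the maximum), which at 0.25 Hz is a
full grid step; after normalization grid-aligned tones between 0.10 and
0.34 Hz peak exactly on-grid.  Granularity is 60·0.01 = 0.6 bpm.

### Agreement statistics

ICC(A,1) — two-way model, absolute agreement, single measure — is computed
from the ANOVA mean squares, with the confidence interval from the
F-distribution construction using a Satterthwaite-approximated denominator
degree of freedom.  Bland–Altman limits use the fixed 1.96 normal multiplier
(not a t quantile) on the (N−1)-denominator SD of differences.  Stratified
(per-source) and combined computation are both available.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| α (window shape) | 4.0728 | – | endpoint taps ≈ 0.025% of the peak, so the discrete window keeps a Gaussian (monotone low-pass) spectrum; 2.45 (endpoints < 5%) is the admissible floor |
| ε (window scale) | 1.8 | – | multiplies the mean extrema spacing; admissible range 1.1–3 |
| band | 0.09–0.35 | Hz | physiologic respiration, 5.4–21 bpm; adjustable per application |
| window length | 20 | s | non-overlapping analysis windows; 11.11 s (one cycle at 0.09 Hz) is the hard floor |
| df (reference grid) | 0.01 | Hz | reference granularity 0.6 bpm |
| energy thresholds | 1e6 / 1e-3 | – | sifting stop criteria, see above |

## Synthetic data

The generator produces the structure the estimator relies on and nothing
more: `resp(t)` is a unit sinusoid with phase-continuous piecewise-constant
rate (so paced-breathing switches, e.g. 6 → 10 bpm mid-record, produce no
amplitude jump), and the surrogate is
`(1 + am_depth·resp)·cos(2π·f_c·t) + baseline_gain·resp (+ AWGN)` with
defaults f<sub>c</sub> = 1.2 Hz (72 bpm), am_depth = 0.3,
baseline_gain = 0.5, f<sub>s</sub> = 100 Hz, 60 s.  AWGN variance is set from
the realized signal power and the requested SNR (5 dB is the stress case).
All randomness flows through one seeded generator.

What the surrogates do **not** emulate: PPG/SCG beat morphology (harmonics of
the cardiac line), motion artefacts, sensor saturation, or irregular
spontaneous breathing.  Passing tests therefore demonstrate the mechanics of
the pipeline — separation, IF tracking, screening, selection — under the
assumed modulation structure, not clinical performance on real recordings.

## Numerical choices and degenerate inputs

- Reconstruction is exact by construction (telescoping); tests bound it at
  1e-9 relative.
- The moving average is evaluated as a valid-mode convolution; equality with
  the O(N·M) direct sum is tested at 1e-12.
- Ties in the band argmax of the reference spectrum resolve to the lowest
  frequency; a perfectly flat spectrum is flagged low-confidence.
- All-constant input decomposes to zero IMFs with residual = input; NaN
  samples are rejected at `SignalRecord` construction with the offending
  index named.
- Perfect agreement (MSE = 0) makes the ICC interval degenerate at 1;
  constant paired data make ICC undefined and raise.
- Resampling is rational-factor polyphase with anti-aliasing
  (denominator capped at 1000); upsampling beyond 10× warns.

## Problem sizes

Default test and acceptance runs use 60-s records at 100 Hz (6000 samples),
20-s windows for segmented estimation, a 6–18 bpm rate grid at ∞/10/5 dB
SNR, and agreement samples of 25–4650 pairs — comfortable desk-scale sizes
chosen so the whole suite runs in seconds.

## Known limitations

- **Windowed edge bias.**  With no IF trimming (kept to match the plain
  all-samples mean), 20-s windows show an upward RR bias of ~1–3 bpm on the
  surrogates because the edge fifth of the IF track is distorted; 60-s
  records reduce this to < 0.1 bpm.  Paced-change tracking is unaffected in
  direction and magnitude of the step.
- Respiration energy can split across two adjacent IMFs when interleaved
  ripple inflates the extrema count; the min-std rule still selects the
  dominant fragment.
- The reference estimator inherits the 0.6-bpm grid granularity.
- Rates outside 5.4–21 bpm (neonates, exercise tachypnea) need a re-tuned
  band.
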