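# Methods

## What the synthetic generator emulates

Real simultaneous finger recordings of optical (PPG red/infrared) and
piezoelectric (FCG) pulse waves with a reference ECG are not publicly
deposited, so `pulsewave.synthgen` produces stand-ins with *exactly
known* fiducial geometry. A simulated recording consists of:

- an **ECG** built from Gaussian P/Q/R/S/T lobes per beat (R lobe 20 ms
  FWHM, unit amplitude). This is sufficient for QRS detection and makes
  no further physiological claim;
- three **pulse-wave channels** (`ppg_r`, `ppg_ir`, `fcg`) sharing one
  per-beat template, each delayed after the R-peak by its channel's
  pulse arrival time (PAT = R-peak → systolic peak). Defaults follow the
  published across-subject means: 483 ms (red), 485 ms (infrared),
  315 ms (piezo), i.e. a constant ~168/170 ms mechanical-before-optical
  offset;
- **respiration**: multiplicative amplitude modulation
  `1 + am_depth·sin(2πf_b t)` on the pulses plus an additive baseline
  `baseline_amp·sin(2πf_b t + φ)` with `f_b = 0.25 Hz` (15 breaths/min);
- additive white noise, and optional sub-sample channel skew on the
  optical channels (bounded at 0.5 ms, the acquisition's stated limit;
  default 0);
- raw optical polarity: `ppg_r`/`ppg_ir` are emitted inverted (a pulse
  is a *drop* in transmitted/reflected light), so the preprocessing
  reversal step is genuinely exercised.

Sampling is 200 Hz; RR intervals are Normal(mean_rr, rr_sd) truncated
above `max(0.3 s, t_dia + 2 samples)` (a beat cannot end before its
diastolic anchor). The record spans exactly the sum of the RR draws;
the first R-peak sits 0.2 s after record start, so the first and last
beats are edge-truncated and marked `partial` in the ground truth.

The generator does **not** emulate: motion artifacts, arrhythmia or
ectopy, sensor-specific transfer functions, SpO₂/absorbance physics,
powerline interference, or slow vasomotor amplitude drift. A green
recovery test therefore establishes that the pipeline is unbiased on
clean, stationary pulse trains — not that it is robust to artifacts,
which the source protocol handled by manual exclusion.

### Unreported parameters, chosen once

The study reports no respiratory modulation depth or noise level.
Defaults (relative to a unit systolic height) are: `baseline_amp = 0.1`,
`am_depth = 0.1`, `noise_sd = 0.01`, values typical of a clean resting
finger recording; they are config fields, not constants. The
subject-matched morphology helper uses `t_dia = 450 ms` for the
diastolic-peak time, which summary tables do not report.

## Beat template: exact anchors under band-limiting

Each beat interpolates its five anchors — foot (0, 0), systolic peak
(t_up, h1), dicrotic notch (t_i, h2), diastolic peak (t_dia, h3), next
foot (T, 0) — with **zero slope at every anchor**, so the anchors are
the waveform's only local extrema and ground truth is exact by
construction.

The interpolant is a chain of quintic segments with the **anchor
curvature matched from both sides to the sharper of the two adjoining
zero-slope cubics**. The naive choice (piecewise cubic with zero-slope
anchors) leaves a curvature discontinuity at each anchor, and any
band-limited view of the waveform — 200 Hz sampling, the 20 Hz
zero-phase low-pass — shifts a curvature-kinked extremum 2–4 ms toward
its flatter side, which is the same order as the recovery tolerances
the package is tested against. Matching the curvature (locally C²,
quadratic extremum) removes that first-order shift; taking the
*sharper* side keeps each extremum maximally localized against the
detrending leakage described below. Where the prescribed end curvatures
would make a gentle segment non-monotone, they are scaled back toward
the plain cubic's until the segment is monotone (verified on a sampled
grid), so no spurious extrema can appear; this was fuzz-tested over
hundreds of random morphologies.

## Preprocessing is not fiducially transparent — quantified

The published conditioning chain is reproduced exactly: resample to
1 kHz (polyphase, DC bypassed around the filter), 4th-order Butterworth
20 Hz low-pass run forward and backward (zero phase, 8th-order
magnitude), Savitzky–Golay baseline extraction (order 3, 1501-sample
frame at 1 kHz) subtracted from the signal, polarity reversal of the
optical channels, and a 0.5–40 Hz zero-lag band-pass for the ECG (SOS
realization; pad length scaled to the 0.5 Hz corner's settling time).

A 1.5 s / 3rd-order Savitzky–Golay smoother is **not** a pure baseline
estimator at pulse rates: its frequency response passes ~29% of a
1.04 Hz tone (and ~5% of the second harmonic), so subtracting the
"baseline" removes a slice of the pulse fundamental itself. The removed
component has slope up to ~0.6 amplitude-units/s at the fiducial
points, displacing each extremum by ≈ slope/curvature. With the
curvature-matched template this leaves residual biases (noise-free,
full chain) of roughly −1 ms at foot and systolic peak, −2 ms at the
notch, and up to ~10 ms at the very flat diastolic peak. These are
*common-mode* — both sensors are displaced identically, so delays,
NCC lags and cross-sensor agreement are unaffected — but they set the
floor for absolute anchor-recovery tests, which assert means within
2 ms and per-beat errors within 5–15 ms depending on marker sharpness.
Detection on an unfiltered clean 1 kHz signal recovers every marker
within one sample.

Polarity reversal is conditional: an optical channel is inverted only
if its detrended pulses point downward (negative sample skewness — the
brief, large systolic lobe dominates the third moment). This makes a
second application of the pipeline near-idempotent; the residual
second-pass change is the Savitzky–Golay stage removing another ~20% of
the fundamental, bounded in tests at 20% RMS with waveform correlation
> 0.98.

## Detection choices

- **R-peaks**: classic Pan–Tompkins — 5–15 Hz band-pass, five-point
  derivative, squaring, 150 ms moving-window integration, dual adaptive
  thresholds with 200 ms refractory and half-threshold search-back —
  followed by refinement to the ECG maximum in a 150 ms window before
  the integration peak. Upright R waves are assumed.
- **Search windows**: markers are sought in (R, R + 0.95·median RR].
  With finger PATs of 0.3–0.5 s the diastolic peak falls ~0.83·RR after
  the R-peak, while the next beat's upstroke cannot begin before
  R + RR (PAT > t_up), so the window is safe on both sides. The foot is
  the global minimum between the R-peak and the systolic peak (the
  intersecting-tangent definition is deliberately not used); the notch
  is the sharpest local minimum after the peak (largest positive second
  difference, earliest on ties within 5%); the diastolic peak is the
  first local maximum after the notch.
- **Sub-sample refinement**: every marker time/amplitude is refined by
  a three-point parabolic fit, giving sub-millisecond localization at
  1 kHz.
- **Edge guard**: beats whose window intrudes into the first or last
  0.75 s (half the detrending frame, where zero-phase filters have edge
  transients) are flagged `partial` and excluded downstream; beat
  periods T use successor feet from complete beats only.
- **ECG-free fallback**: if no R-peaks are supplied, surrogate windows
  one autocorrelation-period apart are used; off unless requested.

## Cross-correlation conventions

NCCF uses whole-segment means and norms; after centering, the shorter
segment is zero-padded (out-of-range samples count as the mean).
Positive lag means the *second* signal is delayed — with arguments
ordered (mechanical, optical), the published finding of optics lagging
mechanics appears as a positive lag. Defaults: ±0.5 s lag search for
whole signals, half the median beat length for beat pairs. Beat pairs
are matched by beat index from R-peak-anchored segmentation between
consecutive feet. Zero-padding costs ~delay/record-length of
correlation on a pure shift, so whole-signal NCC approaches 1 only for
records long relative to the delay; derivatives (orders 1–2) use
Savitzky–Golay differentiation (order 3, ~51 ms window).

## Agreement statistics

OLS (mechanical regressed on optical), R² = squared Pearson r, and
Bland–Altman bias with 1.96·SD limits of agreement on beat-matched
parameter pairs; differences are signed piezo − PPG. Bias significance
is a two-sided one-sample t-test at α = 0.05 (flagged NS at p ≥ 0.05 or
zero-variance differences); no multiple-testing correction is applied,
matching the source analysis. Pooling across subjects is beat-level
concatenation of matched pairs with no per-subject weighting.

## Numerical details and degenerate inputs

- Sample indices are 0-based, intervals half-open; times are seconds
  from record start.
- Identical generator configs (including seed) produce bit-identical
  recordings; every pipeline run writes its resolved config and a
  config hash beside the outputs.
- Recording CSVs are written with 17 significant digits and parsed with
  round-trip float precision, so write→read is bit-exact.
- Degenerate inputs raise informative errors: anchor-ordering
  violations name the offending pair; constant signals are rejected by
  NCCF (zero norm) and regression (zero variance in x); records shorter
  than 2 s cannot initialize QRS thresholds; a flat ECG yields an empty
  peak list rather than an error.

## Known limitations

- The diastolic peak is intrinsically poorly localized after 20 Hz
  low-pass + detrending (shallow curvature); treat `dia_peak_t` and the
  diastolic-delay rows as ±10 ms.
- Pan–Tompkins assumes upright R waves; inverted ECG leads are out of
  scope.
- The t-test convention for Bland–Altman bias is this package's choice;
  the source analysis tool's exact p-value method is undocumented.
- No motion-artifact handling: segments with artifacts must be excluded
  before analysis, as in the source protocol.
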