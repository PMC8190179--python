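# Methods

This note documents the models implemented in `glycodvp`, the numerical and
design choices behind them, what the synthetic-data generator does and does
not emulate, and the known limitations. Everything quantitative stated here
is computed by the test suite or the acceptance script; nothing is asserted
from memory.

## Optical model

Transmitted intensity follows decadic Beer–Lambert attenuation,
`I = I0·10^(−A)`, with absorbance `A = C_a·d` for a homogeneous medium of
absorption coefficient `C_a` [cm⁻¹] and path `d` [cm]. Blood is a mixture
of three hemoglobin species with total concentration fixed at the typical
whole-blood value c_Tot = 150/64500 mol/L; its absorption is the convex
combination

    C_a = c_Tot·(ε_HHb + P_HbO·(ε_HbO − ε_HHb) + P_HbA1c·(ε_HbA1c − ε_HHb))

in the partial molar concentrations P_X. The spectra table
(`glycodvp/data/spectra_default.csv`) stores, at the three device
wavelengths 465/525/615 nm, the molar absorption coefficients of the three
species, their bulk equivalents (molar × c_Tot, kept as rounded literals so
the stored table and the conversion identity can be asserted independently
of one another), and the directly measured bulk coefficients of water and a
lumped dermal "skin baseline". One stored value deserves a remark: the HbO
molar coefficient at 615 nm is 1166.4 M⁻¹cm⁻¹, the value consistent with
both the bulk table (1166.4 × 150/64500 = 2.7126 cm⁻¹) and the numeric
ratio equations it must reproduce.

### The two finger models

**Blood-vessel.** Only vessel blood pulses: a heartbeat changes the optical
path by δd at fixed composition, so the pulsatile absorbance is
δA(λ) = C_a(λ)·δd *exactly*, at any amplitude. Per-beat extraction uses
δA = log10(I_dia/I_sys).

**Whole-finger.** The fingertip is a volume mixture: arterial fraction V_a,
venous V_v, water V_w, dermal baseline as the remainder. A heartbeat
increases V_a by ΔV_a (transient venous/water/baseline changes neglected),
giving ΔC_a = ΔV_a·(μ_art − μ_baseline) and, after linearising the
exponential, the AC/DC fraction ΔI/I = −ln(10)·ΔC_a·d. This model is
*first-order*: its accuracy degrades with pulsatile amplitude (see
"Simulator defaults" below). Per-beat extraction uses
(I_dia − I_sys)/I_mean with the beat mean as the DC operating point.

The whole-finger ratio equations are built from the rounded bulk-constant
literals rather than from full-precision molar products: the published
numeric equations are rounded-table arithmetic, and only this choice
reproduces every printed coefficient at printed precision (the two paths
differ by ~1e-4 relative, far inside any scientific tolerance).

### Inversion

Clearing denominators makes the two ratio equations linear in
(P_HbA1c, P_HbO); the 2×2 Cramer solution has determinants whose R1·R2
cross terms cancel, so both estimators are linear-fractional in (R1, R2)
with a shared denominator. The implementation keeps the raw cofactor
values; comparisons with the published scaled tables divide by 2×10⁷
(blood-vessel) or 10³ (whole-finger). Estimates are invariant to any common
rescaling of either the equation triples or the coefficient sextets
(property-tested). Degenerate inputs — proportional triples, or a ratio
pair on the denominator's zero line — raise typed errors; the zero test is
relative (|den| ≤ 1e-12 × the largest coefficient) so that compositions
constructed on the singular plane are caught despite rounding.

Out-of-range fractions on noisy input are returned as-is and flagged, not
clipped: the stage-2 calibrator is designed to absorb model error, and
clipping would hide it.

## Signal processing

* **Filtering**: second-order Butterworth low-pass at 8 Hz, applied
  forward–backward (zero phase) so the systolic/diastolic landmarks are not
  shifted; the effective magnitude response is the squared single-pass
  response.
* **Beat segmentation**: trough-to-trough on the 615 nm channel (strongest
  transmission), minimum beat period 0.33 s, trough prominence at 25 % of
  the channel's AC range; windows are 0-based half-open and contiguous.
* **Feature extraction**: the systolic and diastolic *instants* are located
  (argmin/argmax within the beat) on the channel with the largest relative
  AC range, and all three channels are read at those two common instants.
  Reading at common instants rather than taking per-channel sample extrema
  matters twice over: (i) the pulse phase is shared across channels, so any
  sampling deficit at the extrema cancels from the inter-channel ratios,
  keeping the blood-vessel identity exact to machine precision; and (ii)
  the extreme value of ~30 noisy samples is biased high by about 1.6
  standard deviations of the filtered noise — on the weakly pulsatile red
  channel that bias would inflate amplitudes by a beat-length-dependent
  factor, i.e. by something that varies with heart rate across subjects and
  that the covariate-based calibrator cannot learn. Common-instant reads
  make the noise zero-mean instead.
* **Cleaning**: non-finite ratio rows are dropped, then rows are kept only
  if each ratio column lies within mean ± 0.8416·SD (the central 60 %
  normal interval), intersected across columns; zero-spread columns keep
  all rows. The alternative reading (20th–80th percentile band) was
  considered and not taken; the normal-quantile band is the literal
  "confidence interval around the mean". All SDs in the package use the
  n−1 convention.

## Calibration

Stage 1 regresses the model-consistent ratios (forward equations evaluated
at the reference %HbA1c/%SpO₂ of the *training* subjects) on the signal
ratios plus finger width and BMI; stage 2 regresses the references on the
normalized estimates obtained by pushing stage-1 output through the inverse
model. Both stages are gradient-boosted tree ensembles (XGBoost) with 100
trees, depth 3, learning rate 0.1 — explicit, overridable defaults — run
single-threaded with seeded determinism. Training rows are beat-level with
subject-constant targets, in a canonical sort order so fitting is invariant
to how beats were listed. Subject-level estimates are the arithmetic mean
of beat-level final estimates.

Cross-validation is leave-one-out at the subject level; folds follow
subject-id sort order, the test subject's references never enter its fold's
training tables, and each `LOOCVResults` carries a fold manifest (test
subject → sorted training ids) as a serialisable proof of that. A leakage
canary test asserts that deliberately training with the test subject
changes the prediction.

## Synthetic cohort

The generator emulates the study conditions: ~37 Hz sampling, 2-minute
transmissive recordings, 20 subjects; %HbA1c truncated-normal (mean 6.22,
SD 1.10) on [4.9, 9.1]; %SpO₂ truncated-normal (96.55, 1.32) on [93, 99];
finger width 1.30 ± 0.13; BMI 28.86 ± 3.74; heart rate uniform on 60–90
bpm. The pulse waveform is an asymmetric raised cosine (systolic upstroke
one third of the period); its time-mean is exactly 0.5, which cancels the
second-order term of the AC/DC linearisation. References in the cohort
table equal the ground truth (the synthetic analogue of trusting the
invasive reference devices).

### Simulator defaults and their rationale

* Blood-vessel: d₀ = 0.02 cm, δd = 6×10⁻⁴ cm (3 % diameter pulsation,
  giving red-channel AC ≈ 3.6 % of DC). The extraction identity is exact at
  any amplitude, so the choice is driven by device-realistic perfusion.
* Whole-finger: d₀ = 1 cm, V_a = 0.02, V_v = 0.04, V_w = 0.65, venous
  saturation 10 points below arterial (these cancel from estimation and are
  simulator-only), ΔV_a = 2×10⁻⁴ — one percent of the resting arterial
  fraction, red-channel AC ≈ 1 % of DC. The amplitude is deliberately the
  largest value that keeps the estimator's linearisation honest: the
  dominant residual is first-order in amplitude times the sampling deficit
  of the beat extrema, and at this setting the worst noise-free
  reconstruction error across seeded subjects is 0.06 SpO₂ points
  (tolerance 0.1, measured by the test suite). Larger amplitudes would
  improve SNR but operate the simulator outside the regime the whole-finger
  model assumes.
* Sensor noise: additive Gaussian, SD 0.2 % of the channel DC level.
* Heterogeneity (what stage-1 calibration must remove): per-channel
  multiplicative factors on the pulsatile absorbance with log-loadings on
  z-scored finger width and BMI (465 nm: +0.02/+0.01; 525 nm:
  +0.012/−0.008; 615 nm: −0.01/+0.012) plus a random per-channel log-gain
  of SD 0.004, and a cosmetic static per-channel DC gain (log-SD 0.05) that
  cancels from every ratio. The magnitudes come from an error budget at the
  cohort operating point (sensitivities ≈ 0.33 HbA1c points and ≈ 2.5 SpO₂
  points per 1 % ratio error): the covariate-linked share biases
  uncalibrated estimates by ~0.6 HbA1c points SD — visible, and learnable
  from the covariates — while the random share contributes ~0.16 HbA1c /
  1.4 SpO₂ points SD of irreducible subject bias.

What the generator does **not** emulate: photon scattering and
wavelength-dependent path factors, motion artifacts, baseline wander,
reflective-mode operation, reference-device error, and real anatomical
variability beyond the injected gain heterogeneity. Passing tests on this
cohort therefore demonstrate internal consistency of the pipeline and its
calibration machinery under controlled conditions — not clinical accuracy.

## Known limitations

* The whole-finger model's accuracy under the default noise level is
  SNR-limited: with red-channel pulsation held at ~1 % of DC by the
  linearisation constraint and per-sample noise at 0.2 % of DC, per-beat
  ratio noise at 615 nm (~16 %) exceeds the entire between-subject ratio
  spread (~7 %), so the beat-level calibrator cannot fully separate
  subjects and cross-validated HbA1c MAD saturates near 0.9 points. The
  blood-vessel mode, whose extraction is exact at its larger amplitude,
  reaches MAD ≈ 0.48. A quieter sensor (or ensemble-averaged beats) would
  be needed for the whole-finger model to show its clinical-data
  performance on this simulator.
* Tree-ensemble calibrators cannot extrapolate: subjects at the cohort's
  HbA1c extremes are pulled toward the training range in LOOCV.
* The error-grid C-zone rule uses the 5.7/6.5 %HbA1c diagnostic thresholds
  as a declared convention (the canonical grid exists only for glucose);
  boundaries are configurable.
* Pearson's r is computed on subject-level estimates; it is reported as
  missing for zero-variance inputs rather than NaN-propagated.
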