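# glycodvp

Gray-box estimation of percent glycated hemoglobin (%HbA1c) and oxygen
saturation (%SpO₂) from three-wavelength transmissive digital volume pulse
(DVP) waveforms — the optical pulse signal recorded through a fingertip at
465, 525 and 615 nm.

HbA1c reflects average blood glucose over the preceding months and is the
standard diagnostic for diabetes, but every routine assay needs a blood
sample. This package implements a noninvasive alternative: a mechanistic
Beer–Lambert core that maps pulsatile-intensity ratios between wavelengths
to blood composition, wrapped in a data-driven calibration that absorbs what
the simple optics cannot describe. It is aimed at researchers in biomedical
optics and physiological signal processing who want a complete, testable
reference pipeline — including a forward simulator, so every stage can be
validated without clinical data.

## The model

Blood is treated as a homogeneous mixture of glycated (HbA1c), oxygenated
(HbO) and reduced (HHb) hemoglobin with partial molar concentrations
P_HbA1c, P_HbO and P_HHb = 1 − (P_HbA1c + P_HbO), so that

    %HbA1c = P_HbA1c × 100,    %SpO₂ = P_HbO / (P_HbO + P_HHb) × 100.

Two finger models express the pulsatile absorbance δA(λ) of a heartbeat:

* **blood-vessel model** — only vessel blood pulses; δA(λ) = C_a(λ)·δd with
  C_a the blood absorption coefficient and δd the path-length change, so
  δA is exactly proportional to the molar-absorption mixture;
* **whole-finger model** — a lumped mixture of arterial and venous blood,
  water and a dermal baseline pulses through the arterial volume fraction:
  ΔI/I ≈ −ln(10)·ΔV_a·(μ_a^art(λ) − μ_a^baseline(λ))·d.

Either way, the ratios of pulsatile amplitude between wavelengths

    R1 = δA(525)/δA(615),    R2 = δA(465)/δA(615)

cancel the unknown geometry and are linear-fractional in (P_HbA1c, P_HbO).
Eliminating the two unknowns gives closed-form estimators

    P_HbA1c = (C1·R1 + C2·R2 + C3) / (C4·R1 + C5·R2 + C6)
    P_HbO   = (C7·R1 + C8·R2 + C9) / (C10·R1 + C11·R2 + C12)

whose coefficients are Cramer cofactors of the tabulated absorption
constants (both estimators share a denominator; the sextets are defined up
to scale). Because real fingers differ in width, skin and fat properties, a
two-stage gradient-boosted calibration (ratios first, then values) with
subject-level leave-one-out cross-validation closes the gap between the
idealized optics and reference measurements.

## Worked example

Simulate a 20-subject cohort of 2-minute recordings with known ground truth,
then run the cross-validated pipeline:

```python
from glycodvp import PulseCalibration, SimulationConfig, simulate_cohort

cohort, recordings, truth = simulate_cohort(
    20, config=SimulationConfig(mode="blood_vessel"), seed=0
)
model = PulseCalibration.from_recordings(
    cohort, recordings, finger_model="blood_vessel"
)
res = model.fit_loocv(seed=0)
print(res.summary())
```

which prints (abridged):

```
LOOCVResults: blood_vessel finger model
subjects: 20   beats: 1618   seed: 0
...
%HbA1c: bias -0.025 +/- 0.645  LoA [-1.29, 1.24]  MAD 0.479  RMSE 0.629  R 0.788  mean %CV 2.24
%SpO2: bias +0.073 +/- 2.190  LoA [-4.22, 4.37]  MAD 1.812  RMSE 2.136  R -0.300  mean %CV 0.41  RCF 0.982
EGA zones: A: 19 (95.0%)  B: 0 (0.0%)  C: 1 (5.0%)
```

Reading the numbers: each subject's out-of-fold %HbA1c estimate misses its
reference by 0.48 points on average (MAD), with Bland–Altman bias −0.03 and
95 % limits of agreement of about ±1.3 points; 19 of 20 subjects fall in the
clinically accurate error-grid zone A; the mean per-beat repeatability (%CV)
is 2.2 %. `res.estimates` holds the per-subject table,
`res.beat_estimates` the per-beat estimates, and
`res.plot_bland_altman()` / `res.plot_ega()` draw the agreement figures.

A command-line interface covers the same flow on files:

```
glycodvp simulate --n 20 --seed 0 --out cohort/
glycodvp loocv cohort/ --model both --seed 0 --out results/
glycodvp estimate cohort/S001.csv --calibrator results/calibrator_blood_vessel.pkl \
    --finger-width 1.3 --bmi 28.9 --out est.json
```

## Layout

| module | contents |
| --- | --- |
| `glycodvp.spectra` | chromophore absorption constants (CSV-backed, substitutable) |
| `glycodvp.fingermodel` | ratio equations, Cramer inversion, clinical conversions |
| `glycodvp.signal` | filtering, beat segmentation, ratio extraction, cleaning |
| `glycodvp.simulate` | Beer–Lambert forward simulator and cohort generator |
| `glycodvp.calibration` | two-stage calibration, `PulseCalibration` model / results |
| `glycodvp.metrics` | Bland–Altman, error statistics, RCF, %CV, error grid |
| `glycodvp.cli` | `glycodvp` command-line interface |

See `docs/methods.md` for the modeling assumptions, parameter choices and
known limitations.
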