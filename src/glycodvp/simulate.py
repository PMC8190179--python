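"""Beer-Lambert forward simulator for transmissive DVP recordings.

Produces device-format three-channel recordings with known ground truth, for
testing every downstream stage (filtering, beat segmentation, ratio
extraction, calibration, agreement metrics) without clinical data.

Physics
-------
Transmitted intensity follows decadic attenuation, ``I = I0 * 10^(-A)``.
The absorbance at each wavelength is a baseline plus a pulsatile term driven
by a smooth periodic pulse waveform ``u(t)`` in [0, 1]:

* blood-vessel mode: the optical path through the vessel pulses,
  ``A(t) = C_a * (d0 + delta_d * u(t))`` with the blood absorption ``C_a``
  fixed by the subject's composition;
* whole-finger mode: the arterial volume fraction pulses,
  ``A(t) = (C_a + dC_a * u(t)) * d0`` with
  ``dC_a = dV_a * (mu_art - mu_baseline)``.

The default pulse is an asymmetric raised cosine (systolic upstroke taking a
third of the period).  Its time-mean is exactly 0.5, which cancels the
second-order term of the AC/DC ~ pulsatile-absorbance approximation the
whole-finger estimator relies on.

Subject heterogeneity -- the thing stage-1 calibration must remove -- enters
as per-channel multiplicative factors on the *pulsatile* absorbance, with a
component tied to finger width and BMI (learnable by the calibrator) and a
small random component (irreducible).  Static per-channel gains and additive
Gaussian sensor noise (SD as a fraction of channel DC) complete the model.
No photon transport, scattering or motion artifacts are simulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .fingermodel import PartialConcentrations, WholeFingerComposition, reference_to_partials
from .signal import CHANNELS, DVPRecording, write_device_csv
from .spectra import C_TOT_BLOOD, ChromophoreSpectra, load_default_spectra

__all__ = [
    "SyntheticSubjectSpec",
    "SimulationConfig",
    "CohortParams",
    "absorption_blood",
    "absorption_whole_finger",
    "transmitted_intensity",
    "pulse_waveform",
    "simulate_subject",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SyntheticSubjectSpec:
    """Ground truth and optics of one synthetic subject.

    ``pulse_gain`` holds the per-channel multiplicative factors applied to
    the pulsatile absorbance (subject optical heterogeneity); ``dc_gain``
    rescales whole channels and cancels out of every ratio.
    """

    subject_id: str
    hba1c_pct: float
    spo2_pct: float
    finger_width: float
    bmi: float
    heart_rate_hz: float = 1.2
    pulse_gain: dict[int, float] = field(default_factory=lambda: {wl: 1.0 for wl in CHANNELS})
    dc_gain: dict[int, float] = field(default_factory=lambda: {wl: 1.0 for wl in CHANNELS})
    noise_sd_frac: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.hba1c_pct < 100.0 and 0.0 <= self.spo2_pct <= 100.0):
            raise ValueError("reference percentages out of range")

    @property
    def arterial(self) -> PartialConcentrations:
        return reference_to_partials(self.hba1c_pct, self.spo2_pct)


@dataclass(frozen=True)
class SimulationConfig:
    """Device/geometry configuration shared across a cohort.

    Defaults emulate the study device: ~37 Hz sampling, 2-minute transmissive
    recordings.  The volume fractions and venous composition only matter in
    whole-finger mode (they cancel out of estimation); the venous compartment
    runs 10 saturation points below arterial by default.
    """

    mode: str = "blood_vessel"
    sample_rate: float = 37.0
    duration_s: float = 120.0
    dc_counts: float = 10_000.0  # auto-exposure DC target per channel
    # blood-vessel geometry [cm]
    d0_vessel: float = 0.02
    delta_d: float = 6e-4
    # whole-finger geometry
    d0_finger: float = 1.0
    v_a: float = 0.02
    v_v: float = 0.04
    v_w: float = 0.65
    delta_v_a: float = 2e-4
    venous_spo2_offset: float = -10.0
    systolic_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.mode not in ("blood_vessel", "whole_finger"):
            raise ValueError(f"unknown simulation mode {self.mode!r}")
        if self.v_a + self.v_v + self.v_w + self.delta_v_a > 1.0:
            raise ValueError("volume fractions exceed 1")


def absorption_blood(
    p: PartialConcentrations,
    spectra: ChromophoreSpectra,
    wavelength: int,
    c_tot: float = C_TOT_BLOOD,
) -> float:
    """Bulk absorption [cm^-1] of whole blood with composition ``p``.

    ``c_tot * (eps_HHb + P_HbO*(eps_HbO - eps_HHb) + P_HbA1c*(eps_HbA1c - eps_HHb))``
    -- a convex combination of the pure-species coefficients when ``p`` is in
    range.
    """
    e_hhb = spectra.molar("HHb", wavelength)
    e_hbo = spectra.molar("HbO", wavelength)
    e_a1c = spectra.molar("HbA1c", wavelength)
    return c_tot * (
        e_hhb + p.p_hbo * (e_hbo - e_hhb) + p.p_hba1c * (e_a1c - e_hhb)
    )


def _mu_blood_bulk(p: PartialConcentrations, spectra: ChromophoreSpectra, wl: int) -> float:
    # Same mixture identity on the stored bulk (rounded-table) constants,
    # consistent with the whole-finger ratio equations.
    mu_hhb = spectra.bulk("HHb", wl)
    mu_hbo = spectra.bulk("HbO", wl)
    mu_a1c = spectra.bulk("HbA1c", wl)
    return mu_hhb + p.p_hbo * (mu_hbo - mu_hhb) + p.p_hba1c * (mu_a1c - mu_hhb)


def absorption_whole_finger(
    comp: WholeFingerComposition, spectra: ChromophoreSpectra, wavelength: int
) -> tuple[float, float]:
    """(C_a, dC_a) of the lumped finger at one wavelength [cm^-1].

    ``C_a`` mixes arterial and venous blood, water and the dermal baseline by
    volume; the pulsatile ``dC_a`` involves only the arterial-vs-baseline
    contrast.
    """
    mu_art = _mu_blood_bulk(comp.arterial, spectra, wavelength)
    mu_vein = _mu_blood_bulk(comp.venous, spectra, wavelength)
    mu_w = spectra.bulk("water", wavelength)
    mu_base = spectra.bulk("skin_baseline", wavelength)
    c_a = (
        comp.v_a * mu_art
        + comp.v_v * mu_vein
        + comp.v_w * mu_w
        + comp.v_baseline * mu_base
    )
    d_c_a = comp.delta_v_a * (mu_art - mu_base)
    return c_a, d_c_a


def transmitted_intensity(i0: float, c_a: float, d: float) -> float:
    """Decadic Beer-Lambert attenuation: ``I = I0 * 10^(-C_a d)``."""
    if i0 <= 0:
        raise ValueError("incident intensity must be positive")
    if d < 0:
        raise ValueError("path length must be non-negative")
    return i0 * 10.0 ** (-c_a * d)


def pulse_waveform(
    t: np.ndarray, heart_rate_hz: float, systolic_fraction: float = 1.0 / 3.0
) -> np.ndarray:
    """Asymmetric raised-cosine pulse in [0, 1] (0 = diastolic trough).

    The upstroke occupies ``systolic_fraction`` of the period; each half is a
    cosine arc, so the waveform is smooth and its time-mean is exactly 0.5
    regardless of the asymmetry.
    """
    phase = np.mod(t * heart_rate_hz, 1.0)
    rise = phase < systolic_fraction
    u = np.empty_like(phase)
    u[rise] = 0.5 * (1.0 - np.cos(np.pi * phase[rise] / systolic_fraction))
    u[~rise] = 0.5 * (
        1.0 + np.cos(np.pi * (phase[~rise] - systolic_fraction) / (1.0 - systolic_fraction))
    )
    return u


def _whole_finger_composition(spec: SyntheticSubjectSpec, config: SimulationConfig):
    art = spec.arterial
    venous_spo2 = float(np.clip(spec.spo2_pct + config.venous_spo2_offset, 0.0, 100.0))
    ven = reference_to_partials(spec.hba1c_pct, venous_spo2)
    ven = PartialConcentrations(ven.p_hba1c, ven.p_hbo, compartment="venous")
    return WholeFingerComposition(
        v_a=config.v_a,
        v_v=config.v_v,
        v_w=config.v_w,
        delta_v_a=config.delta_v_a,
        arterial=art,
        venous=ven,
    )


def simulate_subject(
    spec: SyntheticSubjectSpec,
    config: SimulationConfig | None = None,
    spectra: ChromophoreSpectra | None = None,
) -> DVPRecording:
    """Simulate one transmissive recording.

    Deterministic for a given ``spec.seed``.  Negative intensities after
    noise are clipped at a small positive floor (with a warning reporting the
    count).
    """
    config = config if config is not None else SimulationConfig()
    spectra = spectra if spectra is not None else load_default_spectra()
    rng = np.random.default_rng(spec.seed)
    n = int(round(config.duration_s * config.sample_rate))
    t = np.arange(n) / config.sample_rate
    u = pulse_waveform(t, spec.heart_rate_hz, config.systolic_fraction)

    channels: dict[int, np.ndarray] = {}
    n_clipped = 0
    for wl in CHANNELS:
        if config.mode == "blood_vessel":
            c_a = absorption_blood(spec.arterial, spectra, wl)
            a_dc = c_a * config.d0_vessel
            a_pulse = c_a * config.delta_d
        else:
            comp = _whole_finger_composition(spec, config)
            c_a, d_c_a = absorption_whole_finger(comp, spectra, wl)
            a_dc = c_a * config.d0_finger
            a_pulse = d_c_a * config.d0_finger
        # auto-exposure: incident intensity set so the diastolic DC level
        # lands at dc_counts (real sensors integrate longer on dim channels)
        i0 = config.dc_counts * 10.0 ** a_dc
        a_t = a_dc + spec.pulse_gain[wl] * a_pulse * u
        intensity = spec.dc_gain[wl] * i0 * 10.0 ** (-a_t)
        if spec.noise_sd_frac > 0:
            dc_level = float(np.mean(intensity))
            intensity = intensity + rng.normal(
                0.0, spec.noise_sd_frac * dc_level, size=n
            )
        floor = 1e-6 * config.dc_counts
        clipped = intensity < floor
        n_clipped += int(np.sum(clipped))
        intensity = np.where(clipped, floor, intensity)
        channels[wl] = intensity
    if n_clipped:
        warnings.warn(f"{n_clipped} samples clipped at the positive intensity floor")
    return DVPRecording(
        sample_rate=config.sample_rate,
        channels=channels,
        subject_id=spec.subject_id,
        mode="transmissive",
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortParams:
    """Population distributions for cohort generation.

    Defaults reproduce the study cohort statistics: %HbA1c truncated normal
    (mean 6.22, SD 1.10) on [4.9, 9.1]; %SpO2 truncated normal (mean 96.55,
    SD 1.32) on [93, 99]; finger width 1.30 +/- 0.13 and BMI 28.86 +/- 3.74.
    Heart rate is uniform on a resting-adult band.  The heterogeneity
    magnitudes are sized so uncalibrated estimates are visibly biased while
    the covariate-linked share remains learnable (see the methods note).
    """

    hba1c_mean: float = 6.22
    hba1c_sd: float = 1.10
    hba1c_bounds: tuple[float, float] = (4.9, 9.1)
    spo2_mean: float = 96.55
    spo2_sd: float = 1.32
    spo2_bounds: tuple[float, float] = (93.0, 99.0)
    finger_width_mean: float = 1.30
    finger_width_sd: float = 0.13
    finger_width_bounds: tuple[float, float] = (0.95, 1.65)
    bmi_mean: float = 28.86
    bmi_sd: float = 3.74
    bmi_bounds: tuple[float, float] = (18.0, 42.0)
    heart_rate_bounds: tuple[float, float] = (1.0, 1.5)
    noise_sd_frac: float = 0.002
    #: random per-channel log pulse-gain SD (irreducible heterogeneity)
    pulse_gain_log_sd: float = 0.004
    #: covariate loadings of log pulse gain per channel: (z_finger_width, z_bmi)
    pulse_gain_loadings: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {465: (0.02, 0.01), 525: (0.012, -0.008), 615: (-0.01, 0.012)}
    )
    dc_gain_log_sd: float = 0.05


def _draw_truncnorm(rng, mean, sd, bounds, size=None):
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def make_subject_specs(
    n: int, params: CohortParams | None = None, seed: int = 0
) -> list[SyntheticSubjectSpec]:
    """Draw ``n`` subject specs from the population distributions."""
    if n < 3:
        raise ValueError("a cohort needs at least 3 subjects (LOOCV)")
    params = params if params is not None else CohortParams()
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        fw = float(_draw_truncnorm(rng, params.finger_width_mean, params.finger_width_sd, params.finger_width_bounds))
        bmi = float(_draw_truncnorm(rng, params.bmi_mean, params.bmi_sd, params.bmi_bounds))
        z_fw = (fw - params.finger_width_mean) / params.finger_width_sd
        z_bmi = (bmi - params.bmi_mean) / params.bmi_sd
        pulse_gain = {}
        for wl in CHANNELS:
            a_fw, a_bmi = params.pulse_gain_loadings[wl]
            eta = (
                a_fw * z_fw
                + a_bmi * z_bmi
                + rng.normal(0.0, params.pulse_gain_log_sd)
            )
            pulse_gain[wl] = float(np.exp(eta))
        dc_gain = {
            wl: float(np.exp(rng.normal(0.0, params.dc_gain_log_sd))) for wl in CHANNELS
        }
        specs.append(
            SyntheticSubjectSpec(
                subject_id=f"S{i + 1:03d}",
                hba1c_pct=float(_draw_truncnorm(rng, params.hba1c_mean, params.hba1c_sd, params.hba1c_bounds)),
                spo2_pct=float(_draw_truncnorm(rng, params.spo2_mean, params.spo2_sd, params.spo2_bounds)),
                finger_width=fw,
                bmi=bmi,
                heart_rate_hz=float(rng.uniform(*params.heart_rate_bounds)),
                pulse_gain=pulse_gain,
                dc_gain=dc_gain,
                noise_sd_frac=params.noise_sd_frac,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def simulate_cohort(
    n: int,
    params: CohortParams | None = None,
    config: SimulationConfig | None = None,
    seed: int = 0,
    outdir=None,
):
    """Simulate a cohort: recordings plus cohort and ground-truth tables.

    Returns ``(cohort_df, recordings, truth_df)``.  The cohort table uses the
    true values as references (the synthetic analogue of invasive reference
    measurements).  With ``outdir`` set, recordings are written in the device
    CSV dialect alongside ``cohort.csv`` and ``truth.csv``.
    """
    config = config if config is not None else SimulationConfig()
    specs = make_subject_specs(n, params=params, seed=seed)
    recordings: dict[str, DVPRecording] = {}
    cohort_rows, truth_rows = [], []
    for spec in specs:
        rec = simulate_subject(spec, config)
        recordings[spec.subject_id] = rec
        path = f"{spec.subject_id}.csv"
        cohort_rows.append(
            dict(
                subject_id=spec.subject_id,
                finger_width=spec.finger_width,
                bmi=spec.bmi,
                ref_hba1c=spec.hba1c_pct,
                ref_spo2=spec.spo2_pct,
                recording_path=path,
            )
        )
        truth_rows.append(
            dict(
                subject_id=spec.subject_id,
                true_hba1c=spec.hba1c_pct,
                true_spo2=spec.spo2_pct,
                heart_rate_hz=spec.heart_rate_hz,
                seed=spec.seed,
                **{f"pulse_gain_{wl}": spec.pulse_gain[wl] for wl in CHANNELS},
            )
        )
    cohort = pd.DataFrame(cohort_rows)
    truth = pd.DataFrame(truth_rows)
    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        for sid, rec in recordings.items():
            write_device_csv(rec, os.path.join(outdir, f"{sid}.csv"))
        cohort.to_csv(os.path.join(outdir, "cohort.csv"), index=False)
        truth.to_csv(os.path.join(outdir, "truth.csv"), index=False)
    return cohort, recordings, truth
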