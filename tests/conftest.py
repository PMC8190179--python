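import numpy as np
import pandas as pd
import pytest

from glycodvp import (
    PartialConcentrations,
    SubjectRecord,
    build_ratio_equations,
    forward_ratios,
    load_default_spectra,
    reference_to_partials,
)


@pytest.fixture(scope="session")
def spectra():
    return load_default_spectra()


@pytest.fixture(scope="session")
def eqs_bv():
    return build_ratio_equations("blood_vessel")


@pytest.fixture(scope="session")
def eqs_wf():
    return build_ratio_equations("whole_finger")


def make_subject_records(
    n: int,
    finger_model: str = "blood_vessel",
    seed: int = 0,
    beats: int = 40,
    ratio_bias_sd: float = 0.0,
    beat_noise_sd: float = 0.0,
) -> list[SubjectRecord]:
    """Analytic cohort for calibration tests: signal ratios are the forward
    model ratios, optionally scaled by a per-subject multiplicative bias and
    jittered per beat.  Much faster than waveform simulation."""
    rng = np.random.default_rng(seed)
    eqs = build_ratio_equations(finger_model)
    records = []
    for i in range(n):
        hba1c = float(rng.uniform(4.9, 9.1))
        spo2 = float(rng.uniform(93.0, 99.0))
        rp = forward_ratios(reference_to_partials(hba1c, spo2), eqs)
        bias1 = np.exp(rng.normal(0, ratio_bias_sd))
        bias2 = np.exp(rng.normal(0, ratio_bias_sd))
        r1 = rp.r1 * bias1 * np.exp(rng.normal(0, beat_noise_sd, beats))
        r2 = rp.r2 * bias2 * np.exp(rng.normal(0, beat_noise_sd, beats))
        records.append(
            SubjectRecord(
                subject_id=f"T{i + 1:03d}",
                ratios=pd.DataFrame({"r1": r1, "r2": r2}),
                finger_width=float(rng.normal(1.30, 0.13)),
                bmi=float(rng.normal(28.86, 3.74)),
                ref_hba1c=hba1c,
                ref_spo2=spo2,
            )
        )
    return records


@pytest.fixture
def physio_box():
    """Physiological composition box used by round-trip checks."""
    def sample(rng, n):
        return [
            PartialConcentrations(a, o)
            for a, o in zip(rng.uniform(0.04, 0.12, n), rng.uniform(0.85, 0.95, n))
        ]

    return sample
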