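"""Three-wavelength ratio equations of the two gray-box finger models and
their linear-fractional inverses.

Both models reduce the fingertip to a system whose pulsatile absorbance at a
wavelength is linear in the two unknown hemoglobin fractions, the partial
molar concentrations ``P_HbA1c`` and ``P_HbO`` (``P_HHb`` completes to 1).
Taking the ratio of pulsatile absorbance between two wavelengths cancels the
unknown geometry (path-length change or pulsatile arterial volume), leaving

    R1 = (a1*P_HbA1c + b1*P_HbO + k1) / (a3*P_HbA1c + b3*P_HbO + k3)
    R2 = (a2*P_HbA1c + b2*P_HbO + k2) / (a3*P_HbA1c + b3*P_HbO + k3)

with a *shared* denominator (the red 615 nm channel).  The coefficient
triples differ between the models:

* blood-vessel model -- only vessel blood pulses; triples come from the molar
  absorption differences ``eps_X(lambda) - eps_HHb(lambda)`` (and intercept
  ``eps_HHb``);
* whole-finger model -- a homogeneous mix of arterial/venous blood, water and
  a dermal baseline pulses through the arterial volume fraction; triples come
  from bulk coefficients, with the baseline subtracted from the intercept:
  ``mu_X - mu_HHb`` and ``mu_HHb - mu_baseline``.

Because the two ratio equations are linear in (P_HbA1c, P_HbO) once cleared
of denominators, eliminating them yields closed-form linear-fractional
estimators

    P_HbA1c = (C1*R1 + C2*R2 + C3) / (C4*R1 + C5*R2 + C6)
    P_HbO   = (C7*R1 + C8*R2 + C9) / (C10*R1 + C11*R2 + C12)

whose twelve coefficients are Cramer cofactors of the triples (the ``R1*R2``
cross terms cancel).  The sextets are defined only up to a common scale;
estimates are invariant to it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .spectra import (
    C_TOT_BLOOD,
    ChromophoreSpectra,
    WavelengthTriple,
    load_default_spectra,
)

__all__ = [
    "ModelName",
    "PartialConcentrations",
    "RatioPair",
    "RatioEquationCoefficients",
    "InverseCoefficients",
    "ClinicalEstimate",
    "WholeFingerComposition",
    "build_ratio_equations",
    "forward_ratios",
    "solve_inverse",
    "estimate_partials",
    "to_clinical",
    "reference_to_partials",
]

ModelName = Literal["blood_vessel", "whole_finger"]
MODEL_NAMES: tuple[str, ...] = ("blood_vessel", "whole_finger")

#: Normalisation used when comparing the Cramer cofactors to the published
#: coefficient tables (the tables print scaled values without stating the
#: scale; the scale does not affect estimates).
TABLE_SCALE = {"blood_vessel": 2e7, "whole_finger": 1e3}


class DegenerateCompositionError(ZeroDivisionError):
    """A ratio-equation denominator evaluated to zero."""


class EstimationError(ZeroDivisionError):
    """The linear-fractional estimator denominator vanished at (R1, R2)."""


class SingularModelError(ValueError):
    """The two ratio equations are not independent (proportional triples)."""


@dataclass(frozen=True)
class PartialConcentrations:
    """Normalized blood composition: fractions of total hemoglobin.

    ``p_hhb`` is always the completion ``1 - (p_hbo + p_hba1c)``.
    ``compartment`` tags arterial vs venous blood where it matters (only the
    simulator distinguishes them; estimation sees arterial terms only).
    """

    p_hba1c: float
    p_hbo: float
    compartment: str = "arterial"

    @property
    def p_hhb(self) -> float:
        return 1.0 - (self.p_hbo + self.p_hba1c)

    @property
    def in_range(self) -> bool:
        return (
            0.0 <= self.p_hba1c <= 1.0
            and 0.0 <= self.p_hbo <= 1.0
            and self.p_hhb >= 0.0
        )


@dataclass(frozen=True)
class RatioPair:
    """The two inter-wavelength ratios with a provenance tag.

    ``signal`` ratios come from waveform amplitudes, ``model_forward`` from
    evaluating the ratio equations at a known composition, ``calibrated``
    from the stage-1 calibrator.
    """

    r1: float
    r2: float
    provenance: Literal["signal", "model_forward", "calibrated"] = "signal"

    def __post_init__(self) -> None:
        if self.provenance not in ("signal", "model_forward", "calibrated"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass(frozen=True)
class RatioEquationCoefficients:
    """Numerator triples for R1/R2 and the shared denominator triple.

    Each triple is ``(coef_P_HbA1c, coef_P_HbO, constant)``.
    """

    model: str
    wavelengths: WavelengthTriple
    numerator_r1: tuple[float, float, float]
    numerator_r2: tuple[float, float, float]
    denominator: tuple[float, float, float]

    def scaled(self, k: float) -> "RatioEquationCoefficients":
        """All six triples multiplied by ``k`` (estimates are invariant)."""
        if k == 0:
            raise ValueError("scale must be nonzero")
        s = lambda t: tuple(k * x for x in t)  # noqa: E731
        return replace(
            self,
            numerator_r1=s(self.numerator_r1),
            numerator_r2=s(self.numerator_r2),
            denominator=s(self.denominator),
        )


@dataclass(frozen=True)
class InverseCoefficients:
    """The twelve linear-fractional estimator coefficients C1..C12.

    ``(C4, C5, C6) == (C10, C11, C12)`` by construction: both estimators share
    the same denominator, as in the published coefficient tables.
    """

    model: str
    c: tuple[float, ...]  # C1..C12

    def __post_init__(self) -> None:
        if len(self.c) != 12:
            raise ValueError("expected twelve coefficients")

    @property
    def hba1c_numerator(self) -> tuple[float, float, float]:
        return self.c[0:3]

    @property
    def hbo_numerator(self) -> tuple[float, float, float]:
        return self.c[6:9]

    @property
    def denominator(self) -> tuple[float, float, float]:
        return self.c[3:6]

    def scaled(self, k: float) -> "InverseCoefficients":
        if k == 0:
            raise ValueError("scale must be nonzero")
        return replace(self, c=tuple(k * x for x in self.c))


@dataclass(frozen=True)
class ClinicalEstimate:
    """Clinical percentages on the 0-100 scale."""

    hba1c_pct: float
    spo2_pct: float


@dataclass(frozen=True)
class WholeFingerComposition:
    """Partial volume fractions of the whole-finger model.

    ``v_a``/``v_v``/``v_w`` are the arterial, venous and water volume
    fractions; the dermal baseline takes up the remainder.  ``delta_v_a`` is
    the pulsatile arterial increment.  Only the simulator uses the venous
    compartment -- it cancels out of estimation.
    """

    v_a: float
    v_v: float
    v_w: float
    delta_v_a: float
    arterial: PartialConcentrations
    venous: PartialConcentrations

    def __post_init__(self) -> None:
        if min(self.v_a, self.v_v, self.v_w) < 0 or self.delta_v_a < 0:
            raise ValueError("volume fractions must be non-negative")
        if self.v_a + self.delta_v_a + self.v_v + self.v_w > 1.0:
            raise ValueError("volume fractions exceed 1")

    @property
    def v_baseline(self) -> float:
        return 1.0 - (self.v_a + self.v_v + self.v_w)


# ---------------------------------------------------------------------------
# building and evaluating the ratio equations
# ---------------------------------------------------------------------------

def _blood_vessel_triple(spectra: ChromophoreSpectra, wl: int):
    e = lambda sp: spectra.molar(sp, wl)  # noqa: E731
    hhb = e("HHb")
    return (e("HbA1c") - hhb, e("HbO") - hhb, hhb)


def _whole_finger_triple(spectra: ChromophoreSpectra, wl: int):
    # Bulk (Table-2 style) constants: hemoglobin entries are molar values
    # scaled by whole-blood concentration; the baseline enters the intercept.
    mu = lambda sp: spectra.bulk(sp, wl)  # noqa: E731
    hhb = mu("HHb")
    return (mu("HbA1c") - hhb, mu("HbO") - hhb, hhb - mu("skin_baseline"))


def build_ratio_equations(
    model: str,
    spectra: ChromophoreSpectra | None = None,
    wavelengths: WavelengthTriple | None = None,
    c_tot: float = C_TOT_BLOOD,
) -> RatioEquationCoefficients:
    """Instantiate the ratio-equation coefficient triples for a model.

    With the default spectra and wavelengths this reproduces the published
    numeric ratio equations of both models.  ``c_tot`` is accepted for
    interface completeness; it cancels from the blood-vessel ratios and is
    already folded into the stored bulk constants used by the whole-finger
    model.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}")
    spectra = spectra if spectra is not None else load_default_spectra()
    wavelengths = wavelengths if wavelengths is not None else WavelengthTriple()
    triple = _blood_vessel_triple if model == "blood_vessel" else _whole_finger_triple
    return RatioEquationCoefficients(
        model=model,
        wavelengths=wavelengths,
        numerator_r1=triple(spectra, wavelengths.lambda1),
        numerator_r2=triple(spectra, wavelengths.lambda2),
        denominator=triple(spectra, wavelengths.lambda3),
    )


def forward_ratios(
    p: PartialConcentrations, eqs: RatioEquationCoefficients
) -> RatioPair:
    """Evaluate the ratio equations at a known composition."""
    def ev(t):
        return t[0] * p.p_hba1c + t[1] * p.p_hbo + t[2]

    den = ev(eqs.denominator)
    scale = max(abs(x) for x in eqs.denominator)
    if not np.isfinite(den) or abs(den) <= 1e-12 * scale:
        raise DegenerateCompositionError(
            f"ratio-equation denominator is degenerate at {p}"
        )
    return RatioPair(
        r1=ev(eqs.numerator_r1) / den,
        r2=ev(eqs.numerator_r2) / den,
        provenance="model_forward",
    )


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------

def solve_inverse(eqs: RatioEquationCoefficients) -> InverseCoefficients:
    """Eliminate (P_HbA1c, P_HbO) from the two ratio equations.

    Clearing denominators gives two equations linear in the unknowns with
    R-dependent coefficients; the 2x2 Cramer solution has determinants whose
    ``R1*R2`` cross terms cancel, so numerators and denominator are affine in
    (R1, R2).  The resulting sextets are canonical cofactor expressions,
    defined up to a common scale.
    """
    a1, b1, k1 = eqs.numerator_r1
    a2, b2, k2 = eqs.numerator_r2
    a3, b3, k3 = eqs.denominator
    c = (
        # P_HbA1c numerator
        k3 * b2 - k2 * b3,
        k1 * b3 - k3 * b1,
        k2 * b1 - k1 * b2,
        # shared denominator
        a2 * b3 - a3 * b2,
        a3 * b1 - a1 * b3,
        a1 * b2 - a2 * b1,
        # P_HbO numerator
        a3 * k2 - a2 * k3,
        a1 * k3 - a3 * k1,
        a2 * k1 - a1 * k2,
    )
    denom_scale = max(abs(x) for x in c[3:6])
    ref_scale = max(abs(x) for x in (a1, b1, k1, a2, b2, k2, a3, b3, k3)) ** 2
    if denom_scale <= 1e-12 * ref_scale:
        raise SingularModelError(
            "ratio equations are not independent; cannot invert"
        )
    return InverseCoefficients(model=eqs.model, c=c[:6] + c[6:9] + c[3:6])


def estimate_partials(
    r: RatioPair, inv: InverseCoefficients, flag_out_of_range: bool = True
) -> PartialConcentrations:
    """Apply the linear-fractional estimators to a ratio pair.

    Out-of-range fractions (possible on noisy input) are returned as-is --
    the stage-2 calibrator is designed to absorb model error, and clipping
    here would hide it.
    """
    c = inv.c
    den = c[3] * r.r1 + c[4] * r.r2 + c[5]
    scale = max(abs(c[3]), abs(c[4]), abs(c[5]))
    if not np.isfinite(den) or abs(den) <= 1e-12 * scale:
        raise EstimationError(
            f"estimator denominator vanished at (R1={r.r1}, R2={r.r2})"
        )
    p_hba1c = (c[0] * r.r1 + c[1] * r.r2 + c[2]) / den
    p_hbo = (c[6] * r.r1 + c[7] * r.r2 + c[8]) / den
    return PartialConcentrations(p_hba1c=p_hba1c, p_hbo=p_hbo)


def estimate_partials_array(
    r1: np.ndarray, r2: np.ndarray, inv: InverseCoefficients
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`estimate_partials` (degenerate rows become NaN)."""
    c = inv.c
    den = c[3] * r1 + c[4] * r2 + c[5]
    with np.errstate(divide="ignore", invalid="ignore"):
        p_a = np.where(den != 0, (c[0] * r1 + c[1] * r2 + c[2]) / den, np.nan)
        p_o = np.where(den != 0, (c[6] * r1 + c[7] * r2 + c[8]) / den, np.nan)
    return p_a, p_o


# ---------------------------------------------------------------------------
# clinical conversions
# ---------------------------------------------------------------------------

def to_clinical(p: PartialConcentrations) -> ClinicalEstimate:
    """%HbA1c = P_HbA1c*100; %SpO2 = P_HbO/(P_HbO + P_HHb)*100.

    The SpO2 base excludes HbA1c: saturation is computed over the
    oxygen-bindable hemoglobin only.
    """
    bindable = p.p_hbo + p.p_hhb
    if bindable <= 0 or not np.isfinite(bindable):
        raise EstimationError("oxygen-bindable fraction is non-positive; SpO2 undefined")
    return ClinicalEstimate(
        hba1c_pct=p.p_hba1c * 100.0,
        spo2_pct=p.p_hbo / bindable * 100.0,
    )


def reference_to_partials(hba1c_pct: float, spo2_pct: float) -> PartialConcentrations:
    """Invert the clinical conversions (used to build calibration targets).

    ``P_HbA1c = h/100``; ``P_HbO = (s/100)*(1 - P_HbA1c)`` so that the
    saturation over the bindable pool reproduces ``s``.
    """
    if not (0.0 <= hba1c_pct < 100.0):
        raise ValueError("hba1c_pct must be in [0, 100)")
    if not (0.0 <= spo2_pct <= 100.0):
        raise ValueError("spo2_pct must be in [0, 100]")
    p_hba1c = hba1c_pct / 100.0
    p_hbo = (spo2_pct / 100.0) * (1.0 - p_hba1c)
    return PartialConcentrations(p_hba1c=p_hba1c, p_hbo=p_hbo)


# ---------------------------------------------------------------------------
# audit export
# ---------------------------------------------------------------------------

def coefficients_to_json(
    eqs: RatioEquationCoefficients, inv: InverseCoefficients | None = None
) -> str:
    """Serialize the model coefficients for audit / cross-language reuse."""
    if inv is None:
        inv = solve_inverse(eqs)
    doc = {
        "model": eqs.model,
        "wavelengths": {
            "lambda1": eqs.wavelengths.lambda1,
            "lambda2": eqs.wavelengths.lambda2,
            "lambda3": eqs.wavelengths.lambda3,
        },
        "ratio_equations": {
            "numerator_r1": list(eqs.numerator_r1),
            "numerator_r2": list(eqs.numerator_r2),
            "denominator": list(eqs.denominator),
        },
        "inverse_coefficients": list(inv.c),
    }
    return json.dumps(doc, indent=2)


def coefficients_from_json(text: str) -> tuple[RatioEquationCoefficients, InverseCoefficients]:
    doc = json.loads(text)
    wl = WavelengthTriple(**doc["wavelengths"])
    eqs = RatioEquationCoefficients(
        model=doc["model"],
        wavelengths=wl,
        numerator_r1=tuple(doc["ratio_equations"]["numerator_r1"]),
        numerator_r2=tuple(doc["ratio_equations"]["numerator_r2"]),
        denominator=tuple(doc["ratio_equations"]["denominator"]),
    )
    inv = InverseCoefficients(model=doc["model"], c=tuple(doc["inverse_coefficients"]))
    return eqs, inv
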