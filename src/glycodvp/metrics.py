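"""Agreement and repeatability statistics for estimate/reference pairs.

Covers Bland-Altman bias and 95 % limits of agreement, the usual error
statistics (MSE, ME, MAD, RMSE, Pearson's r), the reference closeness factor
(RCF) for SpO2, per-subject percent coefficient of variation (%CV), and an
HbA1c-adapted Clarke error grid.

All standard deviations use the n-1 (sample) convention.  All statistics are
permutation-invariant over the paired samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "AgreementReport",
    "EGAResult",
    "bland_altman",
    "error_stats",
    "rcf",
    "percent_cv",
    "clarke_ega_hba1c",
    "agreement_report",
]

#: 95 % limits-of-agreement multiplier.
LOA_Z = 1.96

#: Relative-error boundary of the clinically-accurate EGA zone.
EGA_ZONE_A_RELATIVE = 0.20

#: Diagnostic %HbA1c thresholds (normal/prediabetes at 5.7, diabetes at 6.5)
#: used by the zone-C rule: an estimate is "uncertain treatment" when it and
#: the reference fall in opposite extreme categories.  The published grid
#: only quotes the 20 % zone-A boundary; this C rule is a declared,
#: configurable convention.
EGA_DIABETES_THRESHOLD = 6.5
EGA_NORMAL_THRESHOLD = 5.7


def _pairs(est, ref):
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("est and ref must be equal-length 1-D sequences")
    return est, ref


@dataclass(frozen=True)
class AgreementReport:
    """Every agreement statistic for one quantity (HbA1c or SpO2)."""

    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    mse: float
    me: float
    mad: float
    rmse: float
    pearson_r: float | None
    rcf: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class EGAResult:
    """Zone assignment of estimate/reference pairs (A accurate, B benign,
    C uncertain treatment)."""

    zones: tuple[str, ...]
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.zones)

    @property
    def percentages(self) -> dict[str, float]:
        return {z: 100.0 * c / self.n for z, c in self.counts.items()}


def bland_altman(est, ref) -> tuple[float, float, tuple[float, float]]:
    """Bias (mean of est - ref), SD of differences, 95 % limits of agreement."""
    est, ref = _pairs(est, ref)
    if len(est) < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    diff = est - ref
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return bias, sd, (bias - LOA_Z * sd, bias + LOA_Z * sd)


def error_stats(est, ref):
    """(mse, me, mad, rmse, pearson_r); r is None for zero-variance input."""
    est, ref = _pairs(est, ref)
    diff = est - ref
    mse = float(np.mean(diff**2))
    me = float(np.mean(diff))
    mad = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(mse))
    pearson = None
    if len(est) >= 2 and np.std(est) > 0 and np.std(ref) > 0:
        pearson = float(np.corrcoef(est, ref)[0, 1])
    return mse, me, mad, rmse, pearson


def rcf(est_spo2, ref_spo2) -> float:
    """Reference closeness factor: mean of 1 - |ref - est|/100.

    Both series on the 0-100 percentage scale; 1 iff perfect agreement.
    """
    est, ref = _pairs(est_spo2, ref_spo2)
    if len(est) == 0:
        raise ValueError("RCF of empty input is undefined")
    return float(np.mean(1.0 - np.abs(ref - est) / 100.0))


def percent_cv(per_beat: pd.DataFrame, value_col: str, subject_col: str = "subject_id"):
    """Per-subject %CV = 100*SD/mean of beat-level estimates, plus cohort mean.

    Subjects with fewer than 2 beats or a non-positive mean get NaN (flagged)
    and are excluded from the cohort mean.
    """
    rows = {}
    for sid, grp in per_beat.groupby(subject_col, sort=True):
        vals = grp[value_col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2 or np.mean(vals) <= 0:
            rows[sid] = np.nan
            continue
        rows[sid] = 100.0 * np.std(vals, ddof=1) / np.mean(vals)
    per_subject = pd.Series(rows, name=f"pct_cv_{value_col}")
    return per_subject, float(per_subject.dropna().mean())


def clarke_ega_hba1c(
    est,
    ref,
    zone_a_relative: float = EGA_ZONE_A_RELATIVE,
    normal_threshold: float = EGA_NORMAL_THRESHOLD,
    diabetes_threshold: float = EGA_DIABETES_THRESHOLD,
) -> EGAResult:
    """HbA1c-adapted Clarke error grid.

    Zone A: within ``zone_a_relative`` (20 %) of the reference.  Zone C:
    beyond that AND the estimate and reference fall in opposite extreme
    diagnostic categories (one diabetic-range, the other normal-range), which
    would steer treatment the wrong way.  Zone B: everything else.
    """
    est, ref = _pairs(est, ref)
    if np.any(ref <= 0):
        raise ValueError("reference values must be positive")
    zones = []
    for e, r in zip(est, ref):
        if abs(e - r) / r <= zone_a_relative:
            zones.append("A")
        elif (r >= diabetes_threshold and e < normal_threshold) or (
            r < normal_threshold and e >= diabetes_threshold
        ):
            zones.append("C")
        else:
            zones.append("B")
    counts = {z: zones.count(z) for z in ("A", "B", "C")}
    return EGAResult(zones=tuple(zones), counts=counts)


def agreement_report(est, ref, spo2_scale: bool = False) -> AgreementReport:
    """Assemble the full agreement report for one quantity.

    With ``spo2_scale`` the RCF (defined on the 0-100 SpO2 scale) is
    included.
    """
    est, ref = _pairs(est, ref)
    bias, sd, (lo, hi) = bland_altman(est, ref)
    mse, me, mad, rmse, pearson = error_stats(est, ref)
    return AgreementReport(
        n=len(est),
        bias=bias,
        sd_diff=sd,
        loa_low=lo,
        loa_high=hi,
        mse=mse,
        me=me,
        mad=mad,
        rmse=rmse,
        pearson_r=pearson,
        rcf=rcf(est, ref) if spo2_scale else None,
    )
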