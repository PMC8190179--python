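"""Two-stage gray-box calibration with subject-level leave-one-out CV.

The estimation chain for one subject is

    cleaned per-beat signal ratios (R1sig, R2sig)
      -> stage 1: gradient-boosted regression of the *model-consistent*
         ratios (R1', R2') on (R1sig, R2sig, finger_width, BMI); R1'/R2' are
         the forward ratio equations evaluated at the reference %HbA1c/%SpO2
         (training subjects only)
      -> inverse finger model: linear-fractional estimators -> normalized
         estimates (h, s) as clinical percentages
      -> stage 2: gradient-boosted regression of the references on (h, s)
      -> per-beat estimates, aggregated by the mean over beats.

Stage 1 absorbs inter-subject optical heterogeneity (finger width, skin/fat
properties); stage 2 absorbs residual model inadequacy.  Both stages train
on beat-level rows with subject-constant targets.

The public surface follows the model/results pattern:
:class:`PulseCalibration` is built from a cohort of
:class:`SubjectRecord`; ``fit()`` trains the calibrators on the full cohort
and ``fit_loocv()`` runs subject-level leave-one-out cross-validation,
returning results objects that carry estimates, agreement diagnostics,
``summary()`` tables and plots.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .fingermodel import (
    MODEL_NAMES,
    RatioPair,
    build_ratio_equations,
    estimate_partials_array,
    forward_ratios,
    reference_to_partials,
    solve_inverse,
)
from .signal import (
    DVPRecording,
    beat_ratio_table,
    clean_ratios,
    lowpass_filter,
    read_device_csv,
    segment_beats,
)

__all__ = [
    "SubjectRecord",
    "CalibrationConfig",
    "CalibratorPair",
    "preprocess_recording",
    "model_reference_ratios",
    "PulseCalibration",
    "PulseCalibrationResults",
    "LOOCVResults",
]

REQUIRED_COVARIATES = ("finger_width", "bmi")
STAGE1_FEATURES = ["r1_sig", "r2_sig", "finger_width", "bmi"]
STAGE2_FEATURES = ["h", "s"]


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's cleaned beat ratios, covariates and references."""

    subject_id: str
    ratios: pd.DataFrame  # columns r1, r2 (cleaned, finite)
    finger_width: float
    bmi: float
    ref_hba1c: float
    ref_spo2: float

    def __post_init__(self) -> None:
        for name in REQUIRED_COVARIATES:
            value = getattr(self, name)
            if value is None or not np.isfinite(value):
                raise ValueError(f"subject {self.subject_id}: missing covariate {name!r}")
        if not (3.0 <= self.ref_hba1c <= 15.0):
            raise ValueError(
                f"subject {self.subject_id}: reference %HbA1c {self.ref_hba1c} "
                "outside the plausible clinical range [3, 15]"
            )
        if not (70.0 <= self.ref_spo2 <= 100.0):
            raise ValueError(
                f"subject {self.subject_id}: reference %SpO2 {self.ref_spo2} "
                "outside the plausible clinical range [70, 100]"
            )

    @property
    def n_beats(self) -> int:
        return len(self.ratios)


@dataclass(frozen=True)
class CalibrationConfig:
    """Gradient-boosted regressor hyperparameters (deterministic given a seed).

    The defaults -- 100 trees, depth 3, learning rate 0.1 -- are explicit,
    overridable choices."""

    n_estimators: int = 100
    max_depth: int = 3
    learning_rate: float = 0.1

    def make_regressor(self, seed: int):
        from xgboost import XGBRegressor

        return XGBRegressor(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            random_state=int(seed) % (2**31 - 1),
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
        )


@dataclass
class CalibratorPair:
    """Fitted stage-1 (ratio) and stage-2 (value) regressors for one model."""

    finger_model: str
    seed: int
    stage1_r1: object
    stage1_r2: object
    stage2_hba1c: object
    stage2_spo2: object
    training_subjects: tuple[str, ...] = ()


def preprocess_recording(
    rec: DVPRecording, finger_model: str, wavelengths=(525, 465, 615)
) -> pd.DataFrame:
    """Filter, segment and extract cleaned per-beat ratios for one model."""
    filtered = lowpass_filter(rec)
    beats = segment_beats(filtered)
    if not beats:
        raise ValueError(f"no beats detected in recording {rec.subject_id!r}")
    table = beat_ratio_table(beats, finger_model, wavelengths)
    return clean_ratios(table)


def model_reference_ratios(subject: SubjectRecord, finger_model: str) -> RatioPair:
    """Stage-1 targets: forward ratios at the subject's reference values."""
    eqs = build_ratio_equations(finger_model)
    rp = forward_ratios(reference_to_partials(subject.ref_hba1c, subject.ref_spo2), eqs)
    return RatioPair(r1=rp.r1, r2=rp.r2, provenance="calibrated")


def _stage1_table(subjects: list[SubjectRecord], finger_model: str) -> pd.DataFrame:
    rows = []
    for s in sorted(subjects, key=lambda s: s.subject_id):
        target = model_reference_ratios(s, finger_model)
        for _, row in s.ratios.iterrows():
            rows.append(
                (s.subject_id, row["r1"], row["r2"], s.finger_width, s.bmi,
                 target.r1, target.r2, s.ref_hba1c, s.ref_spo2)
            )
    table = pd.DataFrame(
        rows,
        columns=["subject_id", "r1_sig", "r2_sig", "finger_width", "bmi",
                 "r1_target", "r2_target", "ref_hba1c", "ref_spo2"],
    )
    # canonical row order: fitting is invariant to how beats were listed
    return table.sort_values(
        ["subject_id", "r1_sig", "r2_sig"], kind="mergesort"
    ).reset_index(drop=True)


def _apply_model(r1: np.ndarray, r2: np.ndarray, inv) -> tuple[np.ndarray, np.ndarray]:
    """Calibrated ratios -> clinical percentages (h, s), NaN where degenerate."""
    p_a, p_o = estimate_partials_array(r1, r2, inv)
    p_hhb = 1.0 - (p_a + p_o)
    bindable = p_o + p_hhb
    with np.errstate(divide="ignore", invalid="ignore"):
        h = p_a * 100.0
        s = np.where(bindable > 0, p_o / bindable * 100.0, np.nan)
    return h, s


def fit_calibrators(
    subjects: list[SubjectRecord],
    finger_model: str,
    config: CalibrationConfig,
    seed: int,
) -> CalibratorPair:
    """Fit stage-1 then stage-2 on beat-level rows from the given subjects."""
    if len(subjects) < 2:
        warnings.warn("fitting calibrators on fewer than 2 subjects; flagged as degenerate")
    table = _stage1_table(subjects, finger_model)
    x1 = table[STAGE1_FEATURES].to_numpy()
    stage1_r1 = config.make_regressor(seed).fit(x1, table["r1_target"].to_numpy())
    stage1_r2 = config.make_regressor(seed + 1).fit(x1, table["r2_target"].to_numpy())

    inv = solve_inverse(build_ratio_equations(finger_model))
    r1_cal = stage1_r1.predict(x1).astype(float)
    r2_cal = stage1_r2.predict(x1).astype(float)
    h, s = _apply_model(r1_cal, r2_cal, inv)
    ok = np.isfinite(h) & np.isfinite(s)
    x2 = np.column_stack([h[ok], s[ok]])
    stage2_h = config.make_regressor(seed + 2).fit(x2, table["ref_hba1c"].to_numpy()[ok])
    stage2_s = config.make_regressor(seed + 3).fit(x2, table["ref_spo2"].to_numpy()[ok])
    return CalibratorPair(
        finger_model=finger_model,
        seed=seed,
        stage1_r1=stage1_r1,
        stage1_r2=stage1_r2,
        stage2_hba1c=stage2_h,
        stage2_spo2=stage2_s,
        training_subjects=tuple(sorted(s.subject_id for s in subjects)),
    )


def predict_subject(
    subject: SubjectRecord, calib: CalibratorPair
) -> tuple[pd.DataFrame, float, float]:
    """Run the full per-beat pipeline; returns (beat table, mean h, mean s).

    Beats whose calibrated ratios are degenerate for the inverse model are
    dropped (flagged in the beat table as NaN before aggregation).
    """
    if subject.n_beats < 1:
        raise ValueError(f"subject {subject.subject_id} has no cleaned beats")
    x1 = np.column_stack(
        [
            subject.ratios["r1"].to_numpy(),
            subject.ratios["r2"].to_numpy(),
            np.full(subject.n_beats, subject.finger_width),
            np.full(subject.n_beats, subject.bmi),
        ]
    )
    inv = solve_inverse(build_ratio_equations(calib.finger_model))
    r1_cal = calib.stage1_r1.predict(x1).astype(float)
    r2_cal = calib.stage1_r2.predict(x1).astype(float)
    h, s = _apply_model(r1_cal, r2_cal, inv)
    est_h = np.full_like(h, np.nan)
    est_s = np.full_like(s, np.nan)
    ok = np.isfinite(h) & np.isfinite(s)
    if ok.any():
        x2 = np.column_stack([h[ok], s[ok]])
        est_h[ok] = calib.stage2_hba1c.predict(x2).astype(float)
        est_s[ok] = calib.stage2_spo2.predict(x2).astype(float)
    beat_table = pd.DataFrame(
        {
            "subject_id": subject.subject_id,
            "r1_cal": r1_cal,
            "r2_cal": r2_cal,
            "h_raw": h,
            "s_raw": s,
            "est_hba1c": est_h,
            "est_spo2": est_s,
        }
    )
    if not ok.any():
        raise ValueError(f"all beats degenerate for subject {subject.subject_id}")
    return beat_table, float(np.nanmean(est_h)), float(np.nanmean(est_s))


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class PulseCalibration:
    """Gray-box %HbA1c / %SpO2 estimation model for a cohort.

    Parameters
    ----------
    subjects
        Cohort of :class:`SubjectRecord` (cleaned beat ratios + covariates +
        references).
    finger_model
        ``"blood_vessel"`` or ``"whole_finger"``.
    config
        Regressor hyperparameters.

    Examples
    --------
    >>> model = PulseCalibration.from_recordings(cohort_df, recordings,
    ...                                          finger_model="blood_vessel")
    >>> res = model.fit_loocv(seed=1)
    >>> print(res.summary())
    """

    def __init__(
        self,
        subjects: list[SubjectRecord],
        finger_model: str = "blood_vessel",
        config: CalibrationConfig | None = None,
    ):
        if finger_model not in MODEL_NAMES:
            raise ValueError(f"unknown finger model {finger_model!r}")
        ids = [s.subject_id for s in subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids: {dupes}")
        self.subjects = sorted(subjects, key=lambda s: s.subject_id)
        self.finger_model = finger_model
        self.config = config if config is not None else CalibrationConfig()

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_recordings(
        cls,
        cohort: pd.DataFrame,
        recordings: dict[str, DVPRecording],
        finger_model: str = "blood_vessel",
        config: CalibrationConfig | None = None,
    ) -> "PulseCalibration":
        """Build from a cohort table and in-memory recordings.

        ``cohort`` needs columns ``subject_id, finger_width, bmi, ref_hba1c,
        ref_spo2``.
        """
        required = {"subject_id", "finger_width", "bmi", "ref_hba1c", "ref_spo2"}
        missing = required - set(cohort.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        subjects = []
        for _, row in cohort.iterrows():
            sid = str(row["subject_id"])
            ratios = preprocess_recording(recordings[sid], finger_model)
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    ratios=ratios[["r1", "r2"]].reset_index(drop=True),
                    finger_width=float(row["finger_width"]),
                    bmi=float(row["bmi"]),
                    ref_hba1c=float(row["ref_hba1c"]),
                    ref_spo2=float(row["ref_spo2"]),
                )
            )
        return cls(subjects, finger_model=finger_model, config=config)

    @classmethod
    def from_cohort_dir(
        cls, path, finger_model: str = "blood_vessel",
        config: CalibrationConfig | None = None,
    ) -> "PulseCalibration":
        """Build from a directory holding ``cohort.csv`` and device CSVs."""
        import os

        cohort = pd.read_csv(os.path.join(path, "cohort.csv"))
        recordings = {
            str(row["subject_id"]): read_device_csv(
                os.path.join(path, row["recording_path"]), subject_id=str(row["subject_id"])
            )
            for _, row in cohort.iterrows()
        }
        return cls.from_recordings(cohort, recordings, finger_model, config)

    # -- fitting ----------------------------------------------------------
    def fit(self, seed: int = 0) -> "PulseCalibrationResults":
        """Fit both calibration stages on the full cohort."""
        calib = fit_calibrators(self.subjects, self.finger_model, self.config, seed)
        rows, beat_tables = [], []
        for s in self.subjects:
            beats, h, sp = predict_subject(s, calib)
            beat_tables.append(beats)
            rows.append((s.subject_id, h, sp, s.ref_hba1c, s.ref_spo2))
        estimates = pd.DataFrame(
            rows, columns=["subject_id", "est_hba1c", "est_spo2", "ref_hba1c", "ref_spo2"]
        )
        return PulseCalibrationResults(
            model=self,
            calibrators=calib,
            estimates=estimates,
            beat_estimates=pd.concat(beat_tables, ignore_index=True),
            seed=seed,
        )

    def fit_loocv(self, seed: int = 0) -> "LOOCVResults":
        """Subject-level leave-one-out cross-validation.

        Folds follow subject-id sort order, so the procedure is fully
        reproducible; the test subject's references never enter its fold's
        training tables.
        """
        if len(self.subjects) < 3:
            raise ValueError("LOOCV needs at least 3 subjects")
        rows, beat_tables, manifest = [], [], {}
        for test in self.subjects:
            train = [s for s in self.subjects if s.subject_id != test.subject_id]
            calib = fit_calibrators(train, self.finger_model, self.config, seed)
            manifest[test.subject_id] = list(calib.training_subjects)
            beats, h, sp = predict_subject(test, calib)
            beat_tables.append(beats)
            rows.append((test.subject_id, h, sp, test.ref_hba1c, test.ref_spo2))
        estimates = pd.DataFrame(
            rows, columns=["subject_id", "est_hba1c", "est_spo2", "ref_hba1c", "ref_spo2"]
        )
        return LOOCVResults(
            model=self,
            estimates=estimates,
            beat_estimates=pd.concat(beat_tables, ignore_index=True),
            fold_manifest=manifest,
            seed=seed,
        )


class _ResultsBase:
    """Shared diagnostics for full-fit and cross-validated results."""

    model: PulseCalibration
    estimates: pd.DataFrame
    beat_estimates: pd.DataFrame
    seed: int

    _COLUMNS = {"hba1c": ("est_hba1c", "ref_hba1c"), "spo2": ("est_spo2", "ref_spo2")}

    def _cols(self, quantity: str):
        try:
            return self._COLUMNS[quantity]
        except KeyError:
            raise ValueError(f"quantity must be 'hba1c' or 'spo2', got {quantity!r}") from None

    def agreement(self, quantity: str) -> _metrics.AgreementReport:
        """Full agreement report (bias, LoA, MSE/ME/MAD/RMSE, Pearson r, RCF)."""
        est_col, ref_col = self._cols(quantity)
        return _metrics.agreement_report(
            self.estimates[est_col], self.estimates[ref_col],
            spo2_scale=(quantity == "spo2"),
        )

    def ega(self) -> _metrics.EGAResult:
        """HbA1c-adapted Clarke error grid on subject-level estimates."""
        return _metrics.clarke_ega_hba1c(
            self.estimates["est_hba1c"], self.estimates["ref_hba1c"]
        )

    def percent_cv(self, quantity: str):
        """(per-subject %CV series, cohort mean %CV) of beat-level estimates."""
        est_col, _ = self._cols(quantity)
        return _metrics.percent_cv(self.beat_estimates, est_col)

    def metrics_dict(self) -> dict:
        """All metrics as a JSON-serialisable dictionary."""
        out = {"finger_model": self.model.finger_model, "seed": self.seed,
               "n_subjects": int(len(self.estimates))}
        for quantity in ("hba1c", "spo2"):
            rep = self.agreement(quantity).to_dict()
            _, mean_cv = self.percent_cv(quantity)
            rep["mean_pct_cv"] = mean_cv
            out[quantity] = rep
        ega = self.ega()
        out["ega"] = {"counts": ega.counts, "percentages": ega.percentages}
        return out

    def summary(self) -> str:
        """Plain-text summary table in the spirit of a regression results page."""
        lines = [
            f"{type(self).__name__}: {self.model.finger_model} finger model",
            f"subjects: {len(self.estimates)}   beats: {len(self.beat_estimates)}   seed: {self.seed}",
            "",
            self.estimates.round(3).to_string(index=False),
            "",
        ]
        for quantity, label in (("hba1c", "%HbA1c"), ("spo2", "%SpO2")):
            a = self.agreement(quantity)
            _, mean_cv = self.percent_cv(quantity)
            extra = f"  RCF {a.rcf:.3f}" if a.rcf is not None else ""
            pearson = f"{a.pearson_r:.3f}" if a.pearson_r is not None else "n/a"
            lines.append(
                f"{label}: bias {a.bias:+.3f} +/- {a.sd_diff:.3f}  "
                f"LoA [{a.loa_low:.2f}, {a.loa_high:.2f}]  MAD {a.mad:.3f}  "
                f"RMSE {a.rmse:.3f}  R {pearson}  mean %CV {mean_cv:.2f}{extra}"
            )
        ega = self.ega()
        pct = ega.percentages
        lines.append(
            "EGA zones: " + "  ".join(
                f"{z}: {ega.counts[z]} ({pct[z]:.1f}%)" for z in ("A", "B", "C")
            )
        )
        return "\n".join(lines)

    # -- plots ------------------------------------------------------------
    def plot_bland_altman(self, quantity: str = "hba1c", ax=None):
        """Bland-Altman scatter with bias and 95 % limits of agreement."""
        import matplotlib.pyplot as plt

        est_col, ref_col = self._cols(quantity)
        est = self.estimates[est_col].to_numpy()
        ref = self.estimates[ref_col].to_numpy()
        bias, sd, (lo, hi) = _metrics.bland_altman(est, ref)
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter((est + ref) / 2, est - ref, s=25)
        for y, style in ((bias, "-"), (lo, "--"), (hi, "--")):
            ax.axhline(y, linestyle=style, color="k", linewidth=1)
        ax.set_xlabel(f"mean of estimate and reference ({quantity})")
        ax.set_ylabel("estimate - reference")
        ax.set_title(f"Bland-Altman, {self.model.finger_model}, {quantity}")
        return ax

    def plot_ega(self, ax=None):
        """Estimate-vs-reference scatter with the 20 % zone-A band."""
        import matplotlib.pyplot as plt

        est = self.estimates["est_hba1c"].to_numpy()
        ref = self.estimates["ref_hba1c"].to_numpy()
        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(min(ref.min(), est.min()) - 0.5, max(ref.max(), est.max()) + 0.5, 50)
        ax.plot(grid, grid, "k-", linewidth=1)
        ax.plot(grid, grid * (1 + _metrics.EGA_ZONE_A_RELATIVE), "k--", linewidth=1)
        ax.plot(grid, grid * (1 - _metrics.EGA_ZONE_A_RELATIVE), "k--", linewidth=1)
        zones = _metrics.clarke_ega_hba1c(est, ref).zones
        colors = {"A": "tab:green", "B": "tab:orange", "C": "tab:red"}
        for zone in ("A", "B", "C"):
            mask = np.array([z == zone for z in zones])
            if mask.any():
                ax.scatter(ref[mask], est[mask], s=25, color=colors[zone], label=f"zone {zone}")
        ax.set_xlabel("reference %HbA1c")
        ax.set_ylabel("estimated %HbA1c")
        ax.legend()
        ax.set_title(f"Error grid, {self.model.finger_model}")
        return ax

    # -- export -----------------------------------------------------------
    def to_csv(self, path) -> None:
        df = self.estimates.copy()
        df.insert(1, "model", self.model.finger_model)
        df.to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.metrics_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class PulseCalibrationResults(_ResultsBase):
    """In-sample results of a full-cohort calibration fit."""

    model: PulseCalibration
    calibrators: CalibratorPair
    estimates: pd.DataFrame
    beat_estimates: pd.DataFrame
    seed: int

    def predict_recording(
        self, rec: DVPRecording, finger_width: float, bmi: float
    ) -> tuple[pd.DataFrame, float, float]:
        """Estimate a new subject (no references needed at test time)."""
        ratios = preprocess_recording(rec, self.model.finger_model)
        subject = SubjectRecord(
            subject_id=rec.subject_id or "new",
            ratios=ratios[["r1", "r2"]].reset_index(drop=True),
            finger_width=finger_width,
            bmi=bmi,
            ref_hba1c=6.0,  # placeholder; never used by prediction
            ref_spo2=96.0,
        )
        return predict_subject(subject, self.calibrators)


@dataclass
class LOOCVResults(_ResultsBase):
    """Out-of-fold results of subject-level leave-one-out cross-validation.

    ``fold_manifest`` maps each test subject to the sorted training-subject
    ids of its fold -- a serialisable proof that the test subject's
    references were absent from every training table.
    """

    model: PulseCalibration
    estimates: pd.DataFrame
    beat_estimates: pd.DataFrame
    fold_manifest: dict[str, list[str]]
    seed: int

    def manifest_hash(self) -> str:
        text = json.dumps(self.fold_manifest, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()
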