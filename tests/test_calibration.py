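import numpy as np
import pandas as pd
import pytest

from glycodvp.calibration import (
    CalibrationConfig,
    PulseCalibration,
    SubjectRecord,
    fit_calibrators,
    model_reference_ratios,
    predict_subject,
)
from glycodvp.fingermodel import forward_ratios, reference_to_partials

from conftest import make_subject_records


class TestReferenceRatios:
    def test_composition_of_forward_and_inverse_conversion(self, eqs_bv):
        s = make_subject_records(1, seed=0)[0]
        target = model_reference_ratios(s, "blood_vessel")
        expected = forward_ratios(reference_to_partials(s.ref_hba1c, s.ref_spo2), eqs_bv)
        assert (target.r1, target.r2) == (expected.r1, expected.r2)
        assert target.provenance == "calibrated"

    def test_identical_references_identical_targets(self):
        a, b = make_subject_records(2, seed=1)
        b = SubjectRecord(b.subject_id, b.ratios, b.finger_width, b.bmi,
                          a.ref_hba1c, a.ref_spo2)
        ta = model_reference_ratios(a, "whole_finger")
        tb = model_reference_ratios(b, "whole_finger")
        assert (ta.r1, ta.r2) == (tb.r1, tb.r2)


class TestSubjectRecordValidation:
    def test_missing_covariate_named(self):
        with pytest.raises(ValueError, match="bmi"):
            SubjectRecord("x", pd.DataFrame({"r1": [1.0], "r2": [1.0]}),
                          finger_width=1.3, bmi=float("nan"),
                          ref_hba1c=6.0, ref_spo2=96.0)

    def test_implausible_references_rejected(self):
        with pytest.raises(ValueError, match="HbA1c"):
            SubjectRecord("x", pd.DataFrame({"r1": [1.0], "r2": [1.0]}),
                          1.3, 28.0, ref_hba1c=20.0, ref_spo2=96.0)


class TestFitting:
    def test_identity_map_learned_in_sample(self):
        """When signal ratios equal the model-consistent targets exactly and
        covariates carry no signal, stage 1 reproduces its training targets
        within 1 %."""
        subjects = make_subject_records(8, seed=2, beats=30)
        subjects = [
            SubjectRecord(s.subject_id, s.ratios, 1.30, 28.86, s.ref_hba1c, s.ref_spo2)
            for s in subjects
        ]
        calib = fit_calibrators(subjects, "blood_vessel", CalibrationConfig(), seed=0)
        for s in subjects:
            target = model_reference_ratios(s, "blood_vessel")
            x = np.array([[target.r1, target.r2, 1.30, 28.86]])
            assert calib.stage1_r1.predict(x)[0] == pytest.approx(target.r1, rel=0.01)
            assert calib.stage1_r2.predict(x)[0] == pytest.approx(target.r2, rel=0.01)

    def test_seed_determinism_and_row_permutation_invariance(self):
        subjects = make_subject_records(6, seed=3, beats=20, beat_noise_sd=0.01)
        calib_a = fit_calibrators(subjects, "blood_vessel", CalibrationConfig(), seed=5)
        calib_b = fit_calibrators(subjects, "blood_vessel", CalibrationConfig(), seed=5)
        shuffled = [
            SubjectRecord(s.subject_id, s.ratios.sample(frac=1, random_state=9),
                          s.finger_width, s.bmi, s.ref_hba1c, s.ref_spo2)
            for s in reversed(subjects)
        ]
        calib_c = fit_calibrators(shuffled, "blood_vessel", CalibrationConfig(), seed=5)
        x = np.array([[5.0, 6.0, 1.3, 28.9]])
        for other in (calib_b, calib_c):
            assert calib_a.stage1_r1.predict(x)[0] == other.stage1_r1.predict(x)[0]
            assert calib_a.stage2_hba1c.predict(np.array([[6.0, 96.0]]))[0] == \
                other.stage2_hba1c.predict(np.array([[6.0, 96.0]]))[0]

    def test_stage2_near_identity_on_well_specified_data(self):
        """Perfect stage-1 input (model-consistent ratios) lets stage 2 learn a
        near-identity map: in-sample MAD below 0.1."""
        subjects = make_subject_records(10, seed=4, beats=30)
        model = PulseCalibration(subjects, "blood_vessel")
        res = model.fit(seed=0)
        assert res.agreement("hba1c").mad < 0.1
        assert res.agreement("spo2").mad < 0.1

    def test_single_subject_fit_warns(self):
        subjects = make_subject_records(1, seed=5)
        with pytest.warns(UserWarning, match="fewer than 2"):
            fit_calibrators(subjects, "blood_vessel", CalibrationConfig(), seed=0)


class TestPredictSubject:
    def test_constant_beats_equal_single_beat_estimate(self):
        subjects = make_subject_records(5, seed=6, beats=25)
        calib = fit_calibrators(subjects, "blood_vessel", CalibrationConfig(), seed=0)
        s = subjects[0]
        beats, h, sp = predict_subject(s, calib)
        single = SubjectRecord(s.subject_id, s.ratios.iloc[:1], s.finger_width,
                               s.bmi, s.ref_hba1c, s.ref_spo2)
        _, h1, sp1 = predict_subject(single, calib)
        # all beats of this analytic subject are identical
        assert h == pytest.approx(h1) and sp == pytest.approx(sp1)
        assert {"est_hba1c", "est_spo2", "h_raw", "s_raw"} <= set(beats.columns)

    def test_no_beats_rejected(self):
        subjects = make_subject_records(4, seed=7)
        calib = fit_calibrators(subjects, "blood_vessel", CalibrationConfig(), seed=0)
        empty = SubjectRecord("E", pd.DataFrame({"r1": [], "r2": []}), 1.3, 28.0, 6.0, 96.0)
        with pytest.raises(ValueError, match="no cleaned beats"):
            predict_subject(empty, calib)


class TestLOOCV:
    def test_fold_structure_and_manifest(self):
        subjects = make_subject_records(6, seed=8, beats=15, beat_noise_sd=0.005)
        res = PulseCalibration(subjects, "blood_vessel").fit_loocv(seed=0)
        assert sorted(res.estimates.subject_id) == sorted(s.subject_id for s in subjects)
        assert len(res.estimates) == 6  # one row per subject
        for test_id, train_ids in res.fold_manifest.items():
            assert test_id not in train_ids
            assert len(train_ids) == 5
        assert len(res.manifest_hash()) == 64

    def test_duplicate_subject_ids_rejected(self):
        subjects = make_subject_records(3, seed=9)
        dup = [subjects[0]] + subjects
        with pytest.raises(ValueError, match="duplicate"):
            PulseCalibration(dup, "blood_vessel")

    def test_too_few_subjects_rejected(self):
        subjects = make_subject_records(3, seed=10)
        with pytest.raises(ValueError, match="at least 3"):
            PulseCalibration(subjects[:2], "blood_vessel").fit_loocv()

    def test_leakage_canary(self):
        """Training with the test subject's references included changes the
        out-of-fold prediction: the honest pipeline must not match the leaky
        one."""
        subjects = make_subject_records(
            8, seed=11, beats=20, ratio_bias_sd=0.02, beat_noise_sd=0.01
        )
        test = subjects[0]
        honest = fit_calibrators(subjects[1:], "blood_vessel", CalibrationConfig(), seed=0)
        leaky = fit_calibrators(subjects, "blood_vessel", CalibrationConfig(), seed=0)
        _, h_honest, _ = predict_subject(test, honest)
        _, h_leaky, _ = predict_subject(test, leaky)
        assert h_honest != pytest.approx(h_leaky, abs=1e-6)
        # the leaky fit memorises its own subject better
        assert abs(h_leaky - test.ref_hba1c) < abs(h_honest - test.ref_hba1c) + 0.5

    def test_loocv_determinism(self):
        subjects = make_subject_records(5, seed=12, beats=15, beat_noise_sd=0.01)
        res_a = PulseCalibration(subjects, "whole_finger").fit_loocv(seed=3)
        res_b = PulseCalibration(subjects, "whole_finger").fit_loocv(seed=3)
        pd.testing.assert_frame_equal(res_a.estimates, res_b.estimates)

    def test_summary_and_exports(self, tmp_path):
        subjects = make_subject_records(5, seed=13, beats=15, beat_noise_sd=0.01)
        res = PulseCalibration(subjects, "blood_vessel").fit_loocv(seed=0)
        text = res.summary()
        assert "%HbA1c" in text and "EGA zones" in text and "LoA" in text
        res.to_csv(tmp_path / "est.csv")
        back = pd.read_csv(tmp_path / "est.csv")
        assert list(back.model.unique()) == ["blood_vessel"]
        metrics = res.metrics_dict()
        assert set(metrics) >= {"hba1c", "spo2", "ega"}
        assert sum(metrics["ega"]["percentages"].values()) == pytest.approx(100.0)

    def test_plots_return_axes(self):
        matplotlib = pytest.importorskip("matplotlib")
        matplotlib.use("Agg")
        subjects = make_subject_records(5, seed=14, beats=10, beat_noise_sd=0.01)
        res = PulseCalibration(subjects, "blood_vessel").fit_loocv(seed=0)
        assert res.plot_bland_altman("hba1c") is not None
        assert res.plot_ega() is not None


class TestNoiseDegradation:
    def test_doubling_noise_does_not_improve_loocv(self):
        """Doubling the simulator's sensor noise does not decrease the
        cross-validated HbA1c MAD (averaged over 3 seeds, with a small
        stochastic tolerance)."""
        from glycodvp.simulate import CohortParams, SimulationConfig, simulate_cohort

        def mean_mad(noise):
            mads = []
            for seed in (0, 1, 2):
                cohort, recs, _ = simulate_cohort(
                    10,
                    params=CohortParams(noise_sd_frac=noise),
                    config=SimulationConfig(duration_s=60),
                    seed=seed,
                )
                res = PulseCalibration(
                    _records_from(cohort, recs), "blood_vessel"
                ).fit_loocv(seed=seed)
                mads.append(res.agreement("hba1c").mad)
            return float(np.mean(mads))

        def _records_from(cohort, recs):
            from glycodvp.calibration import preprocess_recording

            out = []
            for _, row in cohort.iterrows():
                sid = row["subject_id"]
                out.append(
                    SubjectRecord(
                        sid,
                        preprocess_recording(recs[sid], "blood_vessel")[["r1", "r2"]],
                        row["finger_width"], row["bmi"],
                        row["ref_hba1c"], row["ref_spo2"],
                    )
                )
            return out

        assert mean_mad(0.004) >= mean_mad(0.002) - 0.1
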