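"""NTCP model evaluation, featurization and model updating."""

import numpy as np
import pytest
from scipy.special import expit

from ntcpval import ntcp, synthetic, valmetrics
from ntcpval.errors import ConfigError, DataError, FittingError
from ntcpval.ntcp import (
    FeatureVector,
    NTCPModel,
    baseline_score,
    featurize,
    linear_predictor,
    load_builtin_model,
    predict,
    update_model,
)
from ntcpval.registry import FollowUp, PatientRecord

LIPP = load_builtin_model("lipp")


class TestModelEvaluation:
    @pytest.mark.parametrize(
        "category,score", [("none", 0.0), ("mild", 0.459), ("moderate_severe", 1.207)]
    )
    def test_baseline_scores(self, category, score):
        assert baseline_score(LIPP, category) == score

    def test_missing_maps_to_none(self):
        assert baseline_score(LIPP, "missing") == 0.0

    def test_unknown_category_rejected(self):
        with pytest.raises(DataError):
            baseline_score(LIPP, "severe")

    @pytest.mark.parametrize(
        "fv,expected",
        [
            (FeatureVector(0, 0, "none"), -2.2951),
            (FeatureVector(0, 0, "mild"), -1.8361),
            (FeatureVector(10, 10, "none"), -1.1171),
        ],
    )
    def test_linear_predictor_hand_values(self, fv, expected):
        assert linear_predictor(LIPP, fv) == pytest.approx(expected, abs=1e-12)

    def test_predict_is_inverse_logit_of_lp(self):
        fv = FeatureVector(37.2, 51.0, "mild")
        assert predict(LIPP, fv) == pytest.approx(
            expit(linear_predictor(LIPP, fv)), abs=1e-12
        )

    def test_zero_dose_risk(self):
        assert predict(LIPP, FeatureVector(0, 0, "none")) == pytest.approx(0.0915, abs=5e-5)

    def test_monotone_in_dose(self):
        lo = predict(LIPP, FeatureVector(40, 50, "none"))
        hi = predict(LIPP, FeatureVector(50, 50, "none"))
        assert hi > lo

    def test_sqrt_transform(self):
        m = NTCPModel(intercept=-2.0, coef_parotid=0.5, coef_smg=0.25, dose_transform="sqrt")
        assert linear_predictor(m, FeatureVector(16, 4, "none")) == pytest.approx(
            -2.0 + 0.5 * 4 + 0.25 * 2
        )

    def test_negative_dose_rejected(self):
        with pytest.raises(DataError):
            FeatureVector(-1.0, 10.0)


class TestSerialization:
    def test_builtin_models(self):
        recal = load_builtin_model("lipp_recalibrated")
        assert LIPP.intercept == -2.2951
        assert (LIPP.coef_parotid, LIPP.coef_smg) == (0.0996, 0.0182)
        assert recal.intercept == -3.2132
        assert (recal.coef_parotid, recal.coef_smg) == (0.1354, 0.0247)

    def test_json_roundtrip(self, tmp_path):
        path = tmp_path / "m.json"
        LIPP.save(path)
        back = NTCPModel.load(path)
        assert back == LIPP

    def test_unknown_builtin(self):
        with pytest.raises(ConfigError):
            load_builtin_model("nope")


class TestFeaturize:
    def make_record(self, **kw):
        defaults = dict(
            patient_id="p",
            treatment_year=2020,
            tumor_site="oropharynx",
            prescribed_dose=68.0,
            n_fractions=34,
            gland_mean_doses={
                "parotid_ipsi": 28.0,
                "parotid_contra": 16.0,
                "smg_ipsi": 64.0,
                "smg_contra": 46.0,
            },
            followups=[FollowUp(6, 0)],
        )
        defaults.update(kw)
        return PatientRecord(**defaults)

    def test_physical_summary_doses(self):
        fv = featurize(self.make_record(), dose_representation="physical")
        assert fv.parotid_sum_dose == pytest.approx(44.0)
        assert fv.smg_dose == pytest.approx(55.0)

    def test_eqd2_applies_lq_map_to_summaries(self):
        fv = featurize(self.make_record(), dose_representation="eqd2")
        expected = 28.0 * (28 / 34 + 3) / 5 + 16.0 * (16 / 34 + 3) / 5
        assert fv.parotid_sum_dose == pytest.approx(expected)

    def test_smg_sum_combination(self):
        fv = featurize(self.make_record(), dose_representation="physical", smg_combination="sum")
        assert fv.smg_dose == pytest.approx(110.0)

    def test_combined_without_volumes_needs_fallback(self):
        with pytest.raises(ConfigError):
            featurize(self.make_record(), equal_volume_fallback=False)

    def test_dvh_and_summary_paths_agree(self, tmp_path):
        from ntcpval import dosimetry

        rec = self.make_record()
        dvhs = {
            g: synthetic.generate_dvh(d, structure_label=g, absolute_volume=20.0)
            for g, d in rec.gland_mean_doses.items()
        }
        path = tmp_path / "p.csv"
        dosimetry.write_dvh_file(path, dvhs)
        rec_dvh = self.make_record(dvh_file=str(path))
        fv_sum = featurize(rec, dose_representation="physical")
        fv_dvh = featurize(rec_dvh, dose_representation="physical")
        assert fv_dvh.parotid_sum_dose == pytest.approx(fv_sum.parotid_sum_dose, abs=1e-6)
        assert fv_dvh.smg_dose == pytest.approx(fv_sum.smg_dose, abs=1e-6)

    def test_missing_gland_rejected(self):
        rec = self.make_record(gland_mean_doses={"parotid_ipsi": 28.0})
        with pytest.raises(DataError):
            featurize(rec)


def simulate_features(n, rng, model=LIPP, slope=1.0, shift=0.0):
    feats = [
        FeatureVector(rng.uniform(10, 60), rng.uniform(20, 70), "none") for _ in range(n)
    ]
    lp = ntcp.linear_predictors(model, feats)
    y = (rng.random(n) < expit(shift + slope * lp)).astype(float)
    return feats, lp, y


class TestUpdateModel:
    def test_recalibration_preserves_coefficient_ratio_exactly(self, rng):
        _, lp, y = simulate_features(800, rng, slope=1.3)
        m = update_model(LIPP, lp, y, "recalibration")
        assert m.coef_parotid / m.coef_smg == pytest.approx(
            LIPP.coef_parotid / LIPP.coef_smg, rel=1e-12
        )

    def test_recalibration_folding_is_exact(self, rng):
        feats, lp, y = simulate_features(500, rng, slope=1.4, shift=0.3)
        m = update_model(LIPP, lp, y, "recalibration")
        a, b = valmetrics.calibration_slope_intercept(lp, y)
        lp_folded = ntcp.linear_predictors(m, feats)
        assert np.allclose(lp_folded, a + b * lp, atol=1e-8)

    def test_recalibration_slope_consistency_at_large_n(self, rng):
        _, lp, y = simulate_features(100_000, rng)
        m = update_model(LIPP, lp, y, "recalibration")
        b = m.coef_parotid / LIPP.coef_parotid
        assert 0.95 <= b <= 1.05

    def test_intercept_update_near_zero_when_calibrated(self, rng):
        _, lp, y = simulate_features(100_000, rng)
        m = update_model(LIPP, lp, y, "intercept")
        assert m.intercept - LIPP.intercept == pytest.approx(0.0, abs=0.05)
        assert m.coef_parotid == LIPP.coef_parotid

    def test_intercept_update_recovers_shift(self, rng):
        _, lp, y = simulate_features(100_000, rng, shift=-0.6)
        m = update_model(LIPP, lp, y, "intercept")
        assert m.intercept - LIPP.intercept == pytest.approx(-0.6, abs=0.07)

    def test_revision_fits_free_dose_coefficients(self, rng):
        true = NTCPModel(intercept=-3.0, coef_parotid=0.05, coef_smg=0.04)
        feats, _, _ = simulate_features(50_000, rng)
        lp_true = ntcp.linear_predictors(true, feats)
        y = (rng.random(len(feats)) < expit(lp_true)).astype(float)
        lp_orig = ntcp.linear_predictors(LIPP, feats)
        m = update_model(LIPP, lp_orig, y, "revision", features=feats)
        assert m.coef_parotid == pytest.approx(0.05, abs=0.01)
        assert m.coef_smg == pytest.approx(0.04, abs=0.01)

    @pytest.mark.parametrize("level", ["intercept", "recalibration", "revision"])
    def test_updating_never_lowers_log_likelihood(self, rng, level):
        feats, lp, y = simulate_features(600, rng, slope=1.5, shift=-0.4)
        m = update_model(LIPP, lp, y, level, features=feats)
        ll_orig = valmetrics.log_likelihood(expit(lp), y)
        ll_new = valmetrics.log_likelihood(ntcp.predict_many(m, feats), y)
        assert ll_new >= ll_orig - 1e-8

    def test_constant_outcome_rejected(self, rng):
        _, lp, _ = simulate_features(50, rng)
        with pytest.raises(FittingError):
            update_model(LIPP, lp, np.ones(50), "recalibration")

    def test_separation_rejected(self):
        lp = np.linspace(-3, 3, 100)
        y = (lp > 0).astype(float)
        with pytest.raises(FittingError):
            update_model(LIPP, lp, y, "recalibration")

    def test_revision_requires_features(self, rng):
        _, lp, y = simulate_features(100, rng)
        with pytest.raises(ConfigError):
            update_model(LIPP, lp, y, "revision")
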