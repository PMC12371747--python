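"""Calibration, discrimination and goodness-of-fit metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit, logit

from ntcpval import valmetrics
from ntcpval.errors import DataError, FittingError
from ntcpval.valmetrics import (
    auc,
    brier,
    calibration_curve,
    calibration_in_the_large,
    calibration_slope_intercept,
    hosmer_lemeshow,
    log_likelihood,
    validate_predictions,
)


@st.composite
def prediction_sets(draw, min_size=20, max_size=120):
    n = draw(st.integers(min_size, max_size))
    seed = draw(st.integers(0, 2**31 - 1))
    r = np.random.default_rng(seed)
    p = r.uniform(0.02, 0.98, size=n)
    y = (r.random(n) < p).astype(float)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    return p, y


class TestLogLikelihood:
    def test_coin_flip_pair(self):
        assert log_likelihood([0.5, 0.5], [0, 1]) == pytest.approx(2 * np.log(0.5))

    def test_near_perfect_predictions_approach_zero(self):
        eps = 1e-9
        assert log_likelihood([eps, 1 - eps], [0, 1]) == pytest.approx(0.0, abs=1e-8)

    def test_contradicting_degenerate_probability_rejected(self):
        with pytest.raises(DataError):
            log_likelihood([0.0], [1])

    @given(prediction_sets())
    def test_termwise_oracle(self, data):
        p, y = data
        hand = sum(
            np.log(pi) if yi == 1 else np.log(1 - pi) for pi, yi in zip(p, y)
        )
        assert log_likelihood(p, y) == pytest.approx(hand, abs=1e-12)


class TestCalibrationInTheLarge:
    def test_prevalence_predictor_has_zero_intercept(self):
        y = np.array([1.0] * 3 + [0.0] * 7)
        p = np.full(10, 0.3)
        mean_p, obs, a = calibration_in_the_large(p, y)
        assert mean_p == pytest.approx(0.3)
        assert obs == pytest.approx(0.3)
        assert a == pytest.approx(0.0, abs=1e-8)

    def test_consistency_under_the_true_model(self, rng):
        p = rng.uniform(0.05, 0.95, size=100_000)
        y = (rng.random(p.size) < p).astype(float)
        _, _, a = calibration_in_the_large(p, y)
        assert a == pytest.approx(0.0, abs=0.05)

    def test_logit_shift_is_recovered(self, rng):
        p_true = rng.uniform(0.05, 0.9, size=100_000)
        y = (rng.random(p_true.size) < p_true).astype(float)
        p_over = expit(logit(p_true) + 0.5)
        _, _, a = calibration_in_the_large(p_over, y)
        assert a == pytest.approx(-0.5, abs=0.05)

    def test_constant_outcome_rejected(self):
        with pytest.raises(FittingError):
            calibration_in_the_large(np.full(5, 0.4), np.ones(5))


class TestCalibrationSlopeIntercept:
    def test_consistency_monte_carlo(self, rng):
        lp = rng.normal(-0.8, 1.2, size=100_000)
        y = (rng.random(lp.size) < expit(lp)).astype(float)
        a, b = calibration_slope_intercept(lp, y)
        assert 0.95 <= b <= 1.05
        assert -0.05 <= a <= 0.05

    def test_uninformative_predictor_has_zero_slope(self, rng):
        lp = rng.normal(0, 1, size=50_000)
        y = (rng.random(lp.size) < 0.3).astype(float)
        _, b = calibration_slope_intercept(lp, y)
        assert b == pytest.approx(0.0, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(FittingError):
            calibration_slope_intercept(np.linspace(-1, 1, 10), np.zeros(10))


class TestCalibrationCurve:
    def test_cohort_sized_bins(self, rng):
        p = rng.uniform(0.05, 0.9, 674)
        y = (rng.random(674) < p).astype(float)
        curve = calibration_curve(p, y, n_bins=10)
        assert sorted(curve["n"].unique()) in ([67, 68], [67], [68])
        assert curve["n"].sum() == 674
        assert curve["mean_predicted"].is_monotonic_increasing

    def test_constant_predictions_collapse_to_one_bin(self):
        p = np.full(10, 0.3)
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], float)
        with pytest.warns(UserWarning):
            curve = calibration_curve(p, y, n_bins=2)
        assert len(curve) == 1
        assert curve.loc[0, "observed"] == pytest.approx(0.3)

    @given(prediction_sets(min_size=30))
    def test_against_sort_and_slice_oracle(self, data):
        p, y = data
        n_bins = 5
        curve = calibration_curve(p, y, n_bins=n_bins)
        order = np.argsort(p, kind="stable")
        ps, ys = p[order], y[order]
        base, rem = divmod(len(p), n_bins)
        sizes = [base + 1] * rem + [base] * (n_bins - rem)
        start, expected = 0, []
        for s in sizes:
            expected.append((s, ps[start : start + s].mean(), ys[start : start + s].mean()))
            start += s
        if len(curve) == n_bins:  # no tie-merging happened
            for row, (s, mp, ob) in zip(curve.itertuples(), expected):
                assert row.n == s
                assert row.mean_predicted == pytest.approx(mp)
                assert row.observed == pytest.approx(ob)
        assert curve["n"].sum() == len(p)


class TestHosmerLemeshow:
    def test_exact_fit_gives_zero_statistic(self):
        p = np.full(20, 0.3)
        y = np.array(([1] * 3 + [0] * 7) * 2, float)
        with pytest.warns(UserWarning):
            stat, _, pval = hosmer_lemeshow(p, y, g=2)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert pval == pytest.approx(1.0)

    def test_two_bin_hand_example(self):
        p = np.array([0.2] * 50 + [0.4] * 50)
        y = np.array([1] * 15 + [0] * 35 + [1] * 25 + [0] * 25, float)
        stat, df, _ = hosmer_lemeshow(p, y, g=2)
        hand = (15 - 10) ** 2 / (50 * 0.2 * 0.8) + (25 - 20) ** 2 / (50 * 0.4 * 0.6)
        assert stat == pytest.approx(hand, abs=1e-10)

    def test_df_conventions(self, rng):
        p = rng.uniform(0.1, 0.9, 200)
        y = (rng.random(200) < p).astype(float)
        _, df_dev, _ = hosmer_lemeshow(p, y, g=10)
        _, df_ext, _ = hosmer_lemeshow(p, y, g=10, df=10)
        assert (df_dev, df_ext) == (8, 10)

    def test_statistic_nonnegative(self, rng):
        p = rng.uniform(0.1, 0.9, 300)
        y = (rng.random(300) < 0.5).astype(float)
        stat, _, pval = hosmer_lemeshow(p, y)
        assert stat >= 0 and 0 <= pval <= 1


class TestBrierAndAuc:
    def test_brier_perfect_and_coin(self):
        assert brier([0.0, 1.0], [0, 1]) == 0.0
        assert brier([0.5, 0.5], [0, 1]) == 0.25

    def test_brier_of_prevalence_predictor(self):
        y = np.array([1] * 30 + [0] * 70, float)
        prev = y.mean()
        assert brier(np.full(100, prev), y) == pytest.approx(prev * (1 - prev), abs=1e-15)

    @given(prediction_sets())
    def test_brier_meansquare_oracle(self, data):
        p, y = data
        assert brier(p, y) == pytest.approx(np.mean([(pi - yi) ** 2 for pi, yi in zip(p, y)]))

    def test_auc_examples(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert auc([0.4] * 6, [1, 0, 1, 0, 0, 0]) == 0.5
        assert auc([0.8, 0.6, 0.4, 0.2], [1, 0, 1, 0]) == 0.75

    def test_auc_single_class_rejected(self):
        with pytest.raises(DataError):
            auc([0.2, 0.8], [1, 1])

    @given(prediction_sets())
    def test_auc_pair_counting_oracle(self, data):
        p, y = data
        events, nonevents = p[y == 1], p[y == 0]
        wins = sum(
            1.0 if e > ne else 0.5 if e == ne else 0.0 for e in events for ne in nonevents
        )
        assert auc(p, y) == pytest.approx(wins / (len(events) * len(nonevents)), abs=1e-12)

    @given(prediction_sets())
    def test_auc_invariant_under_monotone_transform(self, data):
        p, y = data
        assert auc(expit(3 * logit(p) + 1), y) == pytest.approx(auc(p, y), abs=1e-12)


def test_validation_report_bundle(default_cohort):
    _, _, _, y, lp = default_cohort
    report = validate_predictions(lp, y)
    assert report.n == 674
    assert report.observed_rate == pytest.approx(report.n_events / report.n)
    assert sum(b["n"] for b in report.calibration_curve) == report.n
    assert 0 <= report.brier <= 1
    assert 0 <= report.hl_p <= 1
    assert np.isfinite(report.calibration_slope)
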