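"""Penalized logistic fitting, nested-CV OOF evaluation, calibration, DCA
and operating points."""

import numpy as np
import pandas as pd
import pytest
from conftest import make_expr, make_pheno

from seromir.models import (
    ModelSpec,
    calibration_metrics,
    decision_curve,
    fit_penalized_logistic,
    nested_oof_eval,
    operating_points,
)

SMALL_GRID = {"clf__C": [1.0], "clf__l1_ratio": [0.5]}


class TestPenalizedLogistic:
    def test_unpenalized_limit_separates(self):
        X = np.r_[np.linspace(-3, -1, 20), np.linspace(1, 3, 20)][:, None]
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        model = fit_penalized_logistic(X, y, strength=1e-5)
        p = model.predict_proba(X)[:, 1]
        assert p[:20].max() < 0.05 and p[20:].min() > 0.95

    def test_full_shrinkage_returns_base_rate(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 3))
        y = np.r_[np.ones(70, int), np.zeros(30, int)]
        model = fit_penalized_logistic(X, y, strength=100.0)
        np.testing.assert_allclose(model.coef_, 0.0, atol=1e-6)
        p = model.predict_proba(X)[:, 1]
        np.testing.assert_allclose(p, 0.7, atol=0.05)

    def test_lasso_duplicated_columns_match_coordinate_descent_objective(self):
        # with duplicated columns the lasso objective is flat along the
        # coefficient split (|a|+|b| = |a+b| for same-sign splits), so only
        # the coefficient SUM and the objective value are identified; the
        # fitted model must agree with an independent proximal
        # coordinate-descent oracle on both
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = (x + 0.3 * rng.normal(size=200) > 0).astype(int)
        X = np.column_stack([x, x])
        strength = 0.5
        model = fit_penalized_logistic(X, y, l1_ratio=1.0, strength=strength)
        Xs = model["scale"].transform(model["impute"].transform(X))

        def objective(beta, b0):
            z = Xs @ beta + b0
            nll = np.sum(np.log1p(np.exp(-z)) + (1 - y) * z)
            return nll + strength * np.abs(beta).sum()

        # proximal coordinate descent (lasso-logistic oracle)
        beta, b0 = np.zeros(2), 0.0
        lip = 0.25 * np.max(np.sum(Xs**2, axis=0))
        for _ in range(2000):
            z = Xs @ beta + b0
            p = 1.0 / (1.0 + np.exp(-z))
            b0 -= np.sum(p - y) / (0.25 * len(y))
            for j in range(2):
                g = Xs[:, j] @ (p - y)
                u = beta[j] - g / lip
                beta[j] = np.sign(u) * max(abs(u) - strength / lip, 0.0)
                z = Xs @ beta + b0
                p = 1.0 / (1.0 + np.exp(-z))
        coef = model.coef_
        b0_fit = model.intercept_
        assert objective(coef, b0_fit) == pytest.approx(
            objective(beta, b0), rel=1e-4
        )
        assert coef.sum() == pytest.approx(beta.sum(), rel=0.01)

    def test_weights_change_fit(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 1))
        y = (X[:, 0] + rng.normal(size=80) > 0).astype(int)
        w = np.where(y == 1, 5.0, 1.0)
        m0 = fit_penalized_logistic(X, y, strength=0.1)
        m1 = fit_penalized_logistic(X, y, strength=0.1, weights=w)
        assert m1.intercept_ > m0.intercept_

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_penalized_logistic(np.zeros((5, 1)), np.ones(5, int))


@pytest.fixture(scope="module")
def informative_data():
    pheno = make_pheno(80, 70, seed=3)
    rng = np.random.default_rng(3)
    signal = (pheno["diagnosis"] == "AD").to_numpy(float)
    values = np.vstack(
        [signal * 1.5 + rng.normal(0, 1, len(pheno)),
         rng.normal(size=len(pheno))]
    )
    expr = make_expr(values, feature_ids=["mSig", "mNoise"],
                     sample_ids=list(pheno.index))
    return expr, pheno


class TestNestedOOFEval:
    def test_separable_feature_high_auc_low_brier(self):
        pheno = make_pheno(60, 60, seed=4)
        values = ((pheno["diagnosis"] == "AD").to_numpy(float) * 10)[None, :]
        expr = make_expr(values, feature_ids=["mPerfect"],
                         sample_ids=list(pheno.index))
        spec = ModelSpec(name="perfect", features=("mPerfect",), grid=SMALL_GRID)
        rep = nested_oof_eval(expr, pheno, spec, seed=0, n_bootstrap=200)
        assert rep.auc > 0.99
        assert rep.brier < 0.05

    def test_fixed_seed_reproducible(self, informative_data):
        expr, pheno = informative_data
        spec = ModelSpec(name="sig", features=("mSig",), baseline=("age",),
                         grid=SMALL_GRID)
        r1 = nested_oof_eval(expr, pheno, spec, seed=5, n_bootstrap=100)
        r2 = nested_oof_eval(expr, pheno, spec, seed=5, n_bootstrap=100)
        pd.testing.assert_series_equal(r1.oof_probs, r2.oof_probs)
        assert r1.auc == r2.auc and r1.auc_ci == r2.auc_ci

    def test_noise_feature_barely_moves_auc(self, informative_data):
        expr, pheno = informative_data
        base = nested_oof_eval(
            expr, pheno, ModelSpec(name="a", features=("mSig",), grid=SMALL_GRID),
            seed=6, n_bootstrap=100)
        plus = nested_oof_eval(
            expr, pheno,
            ModelSpec(name="b", features=("mSig", "mNoise"), grid=SMALL_GRID),
            seed=6, n_bootstrap=100)
        assert abs(plus.auc - base.auc) < 0.02

    def test_oof_coverage_every_sample_predicted(self, informative_data):
        expr, pheno = informative_data
        rep = nested_oof_eval(
            expr, pheno, ModelSpec(name="c", features=("mSig",), grid=SMALL_GRID),
            repeats=2, seed=7, n_bootstrap=100)
        assert rep.oof_probs.notna().all()
        assert rep.oof_probs.between(0, 1).all()
        assert len(rep.fold_aucs) == 10  # 5 outer folds x 2 repeats

    def test_summary_mentions_metrics(self, informative_data):
        expr, pheno = informative_data
        rep = nested_oof_eval(
            expr, pheno, ModelSpec(name="d", features=("mSig",), grid=SMALL_GRID),
            seed=8, n_bootstrap=100)
        text = rep.summary()
        assert "OOF AUC" in text and "Brier" in text and "threshold" in text


class TestCalibration:
    def test_well_calibrated_large_sample(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.05, 0.95, size=100_000)
        y = (rng.random(100_000) < p).astype(int)
        ece, _ = calibration_metrics(p, y)
        assert ece < 0.02

    def test_constant_one_with_half_positives(self):
        ece, bins = calibration_metrics(np.ones(10), np.r_[np.ones(5),
                                                           np.zeros(5)].astype(int))
        assert ece == pytest.approx(0.5)
        assert len(bins) == 1

    def test_single_bin_matching_rate_zero_ece(self):
        p = np.full(40, 0.42)
        y = np.r_[np.ones(int(40 * 0.42)), np.zeros(40 - int(40 * 0.42))]
        rate = y.mean()
        p = np.full(40, rate)
        ece, _ = calibration_metrics(p, y.astype(int))
        assert ece == pytest.approx(0.0, abs=1e-12)

    def test_out_of_range_probs_rejected(self):
        with pytest.raises(ValueError):
            calibration_metrics([1.2], [1])


class TestDecisionCurve:
    def test_treat_none_zero_everywhere(self):
        rng = np.random.default_rng(10)
        dc = decision_curve(rng.uniform(size=50),
                            rng.integers(0, 2, size=50))
        np.testing.assert_allclose(dc.treat_none, 0.0)

    def test_treat_all_closed_form_at_prevalence_078(self):
        n = 1000
        n_pos = 780
        y = np.r_[np.ones(n_pos, int), np.zeros(n - n_pos, int)]
        dc = decision_curve(np.full(n, 0.9), y)
        i = np.argmin(np.abs(dc.pt - 0.2))
        assert dc.treat_all[i] == pytest.approx(0.78 - 0.22 * 0.25)

    def test_perfect_predictor_net_benefit_is_prevalence(self):
        y = np.r_[np.ones(30, int), np.zeros(70, int)]
        probs = y.astype(float)
        dc = decision_curve(probs, y)
        np.testing.assert_allclose(dc.net_benefit, 0.3, atol=1e-12)

    def test_net_benefit_bounded_by_prevalence(self):
        rng = np.random.default_rng(11)
        probs = rng.uniform(size=200)
        y = rng.integers(0, 2, size=200)
        dc = decision_curve(probs, y)
        assert np.all(dc.net_benefit <= y.mean() + 1e-12)

    def test_pt_one_rejected(self):
        with pytest.raises(ValueError):
            decision_curve([0.5], [1, 0], pt_grid=[0.5, 1.0])


class TestOperatingPoints:
    def test_perfect_predictor_sens_one_at_high_spec(self):
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        ops = operating_points(y.astype(float), y)
        assert ops.loc["spec_ge_0.90", "sensitivity"] == 1.0
        assert ops.loc["spec_ge_0.90", "specificity"] >= 0.90

    def test_flipped_probs_give_zero_constrained_sensitivity(self):
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        ops = operating_points(1.0 - y.astype(float), y)
        assert ops.loc["spec_ge_0.90", "sensitivity"] == 0.0

    def test_ten_sample_exhaustive_scan(self):
        probs = np.arange(0.1, 1.01, 0.1)
        y = np.r_[np.zeros(5, int), np.ones(5, int)]
        ops = operating_points(probs, y)
        row = ops.loc["spec_ge_0.90"]
        # highest-scoring negative is 0.5, so the threshold must exceed it
        # and the attained sensitivity is 5/5 by enumeration
        assert row["threshold"] > 0.5
        assert row["sensitivity"] == 1.0
        assert row["specificity"] == 1.0

    def test_brier_of_constant_prevalence_predictor(self):
        y = np.r_[np.ones(30, int), np.zeros(70, int)]
        prev = y.mean()
        brier = np.mean((np.full_like(y, prev, dtype=float) - y) ** 2)
        assert brier == pytest.approx(prev * (1 - prev))
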