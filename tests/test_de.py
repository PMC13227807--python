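"""Normalization, filtering, BH and the moderated-t estimator."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from conftest import make_expr, make_pheno
from hypothesis import given, settings
from hypothesis import strategies as st

from seromir import cohort, de
from seromir.de import (
    ModeratedDE,
    bh_adjust,
    compare_covariate_models,
    filter_by_rowsd,
    normalize_log2_quantile,
)


class TestQuantileNormalization:
    def test_identical_columns_fixed_point(self):
        col = np.array([1.0, 5.0, 3.0, 2.0])
        expr = make_expr(np.column_stack([col, col, col]))
        out = normalize_log2_quantile(expr, already_log2=True)
        np.testing.assert_allclose(out.to_numpy(), expr.to_numpy())

    def test_single_sample_is_log2_only(self):
        expr = make_expr([[2.0], [8.0], [1.0]])
        out = normalize_log2_quantile(expr, already_log2=False)
        np.testing.assert_allclose(out.to_numpy().ravel(), [1.0, 3.0, 0.0])

    def test_matches_brute_force_oracle_3x3(self):
        # oracle: replace each column's rank-k value by the mean of all
        # columns' rank-k values
        values = np.array([[5.0, 4.0, 3.0], [2.0, 1.0, 4.0], [3.0, 6.0, 8.0]])
        expr = make_expr(values)
        out = normalize_log2_quantile(expr, already_log2=True).to_numpy()
        expected = np.empty_like(values)
        sorted_cols = np.sort(values, axis=0)
        target = sorted_cols.mean(axis=1)
        for j in range(3):
            ranks = np.argsort(np.argsort(values[:, j]))
            expected[:, j] = target[ranks]
        np.testing.assert_allclose(out, expected)

    def test_ties_get_mean_of_tied_targets(self):
        values = np.array([[1.0, 1.0], [1.0, 2.0], [4.0, 3.0]])
        out = normalize_log2_quantile(make_expr(values), already_log2=True).to_numpy()
        target = np.sort(values, axis=0).mean(axis=1)  # [1, 1.5, 3.5]
        assert out[0, 0] == out[1, 0] == pytest.approx(target[:2].mean())
        assert out[2, 0] == pytest.approx(target[2])

    def test_sorted_columns_equal_reference_and_idempotent(self):
        rng = np.random.default_rng(0)
        expr = make_expr(rng.normal(8, 2, size=(50, 6)))
        out = normalize_log2_quantile(expr, already_log2=True)
        s = np.sort(out.to_numpy(), axis=0)
        np.testing.assert_allclose(s, s[:, [0]] * np.ones((1, 6)), atol=1e-12)
        again = normalize_log2_quantile(out, already_log2=True)
        np.testing.assert_allclose(again.to_numpy(), out.to_numpy(), atol=1e-10)

    def test_nonpositive_raw_intensity_rejected(self):
        with pytest.raises(ValueError, match="log2"):
            normalize_log2_quantile(make_expr([[0.0, 1.0]]), already_log2=False)


class TestRowSDFilter:
    def test_quantile_zero_keeps_all(self):
        expr = make_expr(np.random.default_rng(1).normal(size=(10, 5)))
        assert filter_by_rowsd(expr, 0.0).shape[0] == 10

    def test_linear_interpolation_quantile_oracle(self):
        # rows with SDs 1..8; 0.25-quantile (linear interpolation) = 2.75,
        # so the rows with SD 1 and 2 are removed and 6 remain
        base = np.array([-1.0, 0.0, 1.0]) / np.std([-1.0, 0.0, 1.0], ddof=1)
        values = np.vstack([sd * base for sd in range(1, 9)])
        out = filter_by_rowsd(make_expr(values), 0.25)
        assert list(out.index) == [f"m{i}" for i in range(2, 8)]

    def test_constant_row_removed(self):
        values = np.vstack([np.ones(4), np.arange(4.0), 2 * np.arange(4.0)])
        out = filter_by_rowsd(make_expr(values), 0.25)
        assert "m0" not in out.index

    def test_all_missing_row_warns_and_drops(self):
        values = np.array([[np.nan] * 4, list(np.arange(4.0)), [0, 2, 4, 6.0]])
        with pytest.warns(UserWarning, match="all-missing"):
            out = filter_by_rowsd(make_expr(values), 0.0)
        assert "m0" not in out.index


class TestBHAdjust:
    def test_worked_examples(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1,
                 max_size=30)
    )
    def test_q_dominates_p_and_is_monotone(self, pvals):
        q = bh_adjust(pvals)
        p = np.asarray(pvals)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


@pytest.fixture(scope="module")
def fitted_de():
    cfg = cohort.gse120584_like_config(
        n_ad=60, n_control=40, n_features=120, seed=3
    )
    expr, pheno = cohort.generate_cohort(cfg)
    norm = normalize_log2_quantile(expr, already_log2=True)
    return norm, pheno


class TestModeratedDE:
    def test_identical_groups_give_zero_log2fc(self):
        rng = np.random.default_rng(5)
        block = rng.normal(8, 1, size=(20, 30))
        expr = make_expr(np.hstack([block, block]),
                         sample_ids=[f"S{i:03d}" for i in range(60)])
        pheno = make_pheno(30, 30, seed=5)
        res = ModeratedDE(expr, pheno, covariates=()).fit()
        np.testing.assert_allclose(res.table["log2fc"], 0.0, atol=1e-10)

    def test_prior_df_zero_reproduces_ordinary_t(self, fitted_de):
        norm, pheno = fitted_de
        res = ModeratedDE(norm, pheno, trend=False).fit(prior_df=0)
        X = np.column_stack(
            [
                np.ones(len(pheno)),
                (pheno["diagnosis"] == "AD").astype(float),
                pheno["age"].astype(float),
                (pheno["sex"] == "female").astype(float),
                pheno["apoe4"].astype(float),
            ]
        )
        for g in (0, 7, 55):
            ols = sm.OLS(norm.iloc[g].to_numpy(), X).fit()
            assert res.table["t_mod"].iloc[g] == pytest.approx(ols.tvalues[1])
            assert res.table["p"].iloc[g] == pytest.approx(ols.pvalues[1])

    def test_shrunk_variance_between_observed_and_prior(self, fitted_de):
        norm, pheno = fitted_de
        res = ModeratedDE(norm, pheno, trend=False).fit()
        s0 = res.priors.s0_sq
        lo = np.minimum(res.s_sq, s0) - 1e-12
        hi = np.maximum(res.s_sq, s0) + 1e-12
        assert np.all((res.s_tilde_sq >= lo) & (res.s_tilde_sq <= hi))

    def test_matches_limma_ebayes_oracle(self, fitted_de, tmp_path):
        """Independent cross-check of the EB fit against limma on one matrix."""
        norm, pheno = fitted_de
        norm.to_csv(tmp_path / "expr.tsv", sep="\t")
        X = pd.DataFrame(
            {
                "intercept": 1.0,
                "dx": (pheno["diagnosis"] == "AD").astype(float),
                "age": pheno["age"].astype(float),
                "sex": (pheno["sex"] == "female").astype(float),
                "apoe4": pheno["apoe4"].astype(float),
            }
        )
        X.to_csv(tmp_path / "design.tsv", sep="\t", index=False)
        script = f"""
        suppressMessages(library(limma))
        y <- as.matrix(read.delim('{tmp_path}/expr.tsv', row.names=1))
        design <- as.matrix(read.delim('{tmp_path}/design.tsv'))
        fit <- eBayes(lmFit(y, design), trend=FALSE, robust=FALSE)
        out <- data.frame(t=fit$t[,'dx'], p=fit$p.value[,'dx'],
                          d0=fit$df.prior, s0sq=fit$s2.prior)
        write.table(out, '{tmp_path}/limma.tsv', sep='\\t', quote=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        oracle = pd.read_csv(tmp_path / "limma.tsv", sep="\t", index_col=0)
        res = ModeratedDE(norm, pheno, trend=False).fit()
        assert res.priors.d0 == pytest.approx(oracle["d0"].iloc[0], rel=1e-6)
        assert res.priors.s0_sq == pytest.approx(oracle["s0sq"].iloc[0], rel=1e-6)
        np.testing.assert_allclose(res.table["t_mod"], oracle["t"], rtol=1e-8)
        np.testing.assert_allclose(res.table["p"], oracle["p"], rtol=1e-6)

    def test_signal_features_outrank_null_by_moderated_t(self):
        hits = 0
        for seed in range(10):
            cfg = cohort.gse120584_like_config(
                n_ad=300, n_control=300, n_features=100, noise_sd=0.5,
                cluster_spec=(),
                effect_sizes={m: 1.0 for m in cohort.POSITIVE_CANDIDATES[:10]},
                seed=seed,
            )
            expr, pheno = cohort.generate_cohort(cfg)
            res = ModeratedDE(expr, pheno).fit()
            top10 = set(
                res.table["t_mod"].abs().sort_values(ascending=False).index[:10]
            )
            hits += top10 == set(cohort.POSITIVE_CANDIDATES[:10])
        assert hits >= 9

    def test_rank_deficient_design_names_columns(self, fitted_de):
        norm, pheno = fitted_de
        pheno = pheno.copy()
        pheno["apoe4"] = 1  # constant -> collinear with intercept
        with pytest.raises(ValueError, match="apoe4"):
            ModeratedDE(norm, pheno).fit()

    def test_robust_flag_is_noop_with_warning(self, fitted_de):
        norm, pheno = fitted_de
        with pytest.warns(UserWarning, match="robust"):
            ModeratedDE(norm, pheno, robust=True)

    def test_low_coverage_features_dropped(self, fitted_de):
        norm, pheno = fitted_de
        norm = norm.copy()
        norm.iloc[0, :-5] = np.nan  # < 10 complete per group
        with pytest.warns(UserWarning, match="complete samples"):
            res = ModeratedDE(norm, pheno).fit()
        assert norm.index[0] not in res.table.index


class TestModelComparison:
    def test_identical_results_full_agreement(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(
            {"log2fc": rng.normal(size=30), "q": rng.uniform(0, 0.2, size=30)},
            index=[f"m{i}" for i in range(30)],
        )
        cmp = compare_covariate_models(table, table, alpha=0.05)
        assert cmp.jaccard == pytest.approx(1.0)
        assert cmp.spearman_log2fc == pytest.approx(1.0)

    def test_jaccard_from_constructed_sets(self):
        def fake(sig_ids, all_ids):
            q = [0.01 if f in sig_ids else 0.5 for f in all_ids]
            return pd.DataFrame(
                {"log2fc": np.arange(len(all_ids), dtype=float), "q": q},
                index=all_ids,
            )

        ids = ["a", "b", "c", "d"]
        cmp = compare_covariate_models(fake(["a", "b", "c"], ids),
                                       fake(["b", "c", "d"], ids))
        assert cmp.jaccard == pytest.approx(0.5)
        cmp2 = compare_covariate_models(fake(["a"], ids), fake(["b"], ids))
        assert cmp2.jaccard == 0.0
        cmp3 = compare_covariate_models(fake([], ids), fake([], ids))
        assert cmp3.jaccard is None  # empty union reported missing, not 0
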