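"""Normalization, variance filtering and moderated differential expression.

The core estimator fits, per miRNA, an ordinary least squares model of log2
expression on ``[intercept, diagnosis, covariates]`` and shrinks the residual
variances s_g^2 toward an empirical-Bayes prior s0^2 with prior degrees of
freedom d0:

    s_tilde^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

(d0, s0^2) are estimated by the method of moments on the log residual
variances (matching an F-distribution for s_g^2 / s0^2), and the moderated
t-statistic uses s_tilde with d0 + d_g degrees of freedom.  With the trend
option the prior variance is a smooth (lowess) function of average log2
intensity.  The diagnosis coefficient is reported as log2FC with the
AD-minus-control sign convention (positive = higher in AD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from . import io

__all__ = [
    "normalize_log2_quantile",
    "filter_by_rowsd",
    "bh_adjust",
    "ModeratedDE",
    "DEResults",
    "EBPriors",
    "ModelComparison",
    "compare_covariate_models",
]

MIN_COMPLETE_PER_GROUP = 10


def normalize_log2_quantile(
    expr: pd.DataFrame, already_log2: bool = False
) -> pd.DataFrame:
    """Log2-transform (unless already log2) then quantile-normalize across samples.

    After normalization every sample's sorted value vector equals the
    across-sample mean of sorted vectors; ties within a sample receive the
    mean of their tied positions' target values.  Missing values are kept
    missing; a sample with missing cells is mapped onto the reference
    distribution by interpolating at its observed quantiles.
    """
    values = expr.to_numpy(float)
    if not already_log2:
        if np.nanmin(values) <= 0:
            raise ValueError(
                "non-positive intensities cannot be log2-transformed; "
                "pass already_log2=True if the data are already on log scale"
            )
        values = np.log2(values)
    n_feat, n_samp = values.shape
    if n_samp == 1:
        return pd.DataFrame(values, index=expr.index, columns=expr.columns)

    # reference distribution: mean of per-sample sorted vectors, computed on
    # a common quantile grid so samples with missing cells still contribute
    grid = np.linspace(0.0, 1.0, n_feat)
    ref = np.zeros(n_feat)
    n_used = 0
    for j in range(n_samp):
        col = np.sort(values[~np.isnan(values[:, j]), j])
        if col.size == 0:
            continue
        if col.size == n_feat:
            ref += col
        else:
            ref += np.interp(grid, np.linspace(0.0, 1.0, col.size), col)
        n_used += 1
    if n_used == 0:
        raise ValueError("matrix contains no observed values")
    ref /= n_used

    out = np.full_like(values, np.nan)
    for j in range(n_samp):
        obs = ~np.isnan(values[:, j])
        m = int(obs.sum())
        if m == 0:
            continue
        if m == n_feat:
            ref_m = ref
        elif m == 1:
            ref_m = np.array([np.interp(0.5, grid, ref)])
        else:
            ref_m = np.interp(np.linspace(0.0, 1.0, m), grid, ref)
        out[obs, j] = _assign_sorted_targets(values[obs, j], ref_m)
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def _assign_sorted_targets(col: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Map a column onto sorted target values; tied entries all receive the
    mean of their tied positions' targets."""
    order = np.argsort(col, kind="mergesort")
    sorted_vals = col[order]
    boundaries = np.r_[0, np.nonzero(np.diff(sorted_vals))[0] + 1, col.size]
    assigned = np.empty(col.size)
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        assigned[order[a:b]] = targets[a:b].mean()
    return assigned


def filter_by_rowsd(expr: pd.DataFrame, quantile: float = 0.25) -> pd.DataFrame:
    """Drop low-variability features: keep rows with SD >= the given quantile
    of all row SDs (linear-interpolation quantile definition).

    All-missing rows are excluded with a warning.  Row order is preserved.
    """
    if expr.shape[1] < 2:
        raise ValueError("row-SD filtering needs at least 2 samples")
    if not 0 <= quantile <= 1:
        raise ValueError("quantile must be in [0, 1]")
    n_obs = expr.notna().sum(axis=1)
    all_missing = n_obs == 0
    if all_missing.any():
        warnings.warn(
            f"excluding {int(all_missing.sum())} all-missing feature(s)",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sds = expr.std(axis=1, ddof=1)
    keep_universe = ~all_missing & sds.notna()
    threshold = np.quantile(sds[keep_universe].to_numpy(), quantile)
    return expr.loc[keep_universe & (sds >= threshold)]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg q-values: q_i = min_{p_(j) >= p_(i)} p_(j)*n/j, capped at 1.

    Input order is preserved in the output.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass(frozen=True)
class EBPriors:
    """Moderation hyperparameters: prior df d0 (inf allowed) and prior variance.

    With a variance trend ``s0_sq`` is the geometric-mean prior variance and
    ``s0_sq_trend`` carries the per-feature values.
    """

    d0: float
    s0_sq: float
    s0_sq_trend: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.d0 >= 0 or np.isinf(self.d0)):  # 0 = moderation disabled
            raise ValueError("d0 must be non-negative (possibly infinite)")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")


@dataclass
class ModelComparison:
    jaccard: float | None
    spearman_log2fc: float
    n_sig_a: int
    n_sig_b: int


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def _fit_f_dist(s_sq: np.ndarray, df: np.ndarray, covariate: np.ndarray | None):
    """Moment estimation of the scaled-F prior on residual variances.

    Works on e_g = log(s_g^2) - digamma(d_g/2) + log(d_g/2), whose expectation
    is log(s0^2) + digamma(d0/2) - log(d0/2) and whose excess variance over
    trigamma(d_g/2) is trigamma(d0/2).  With a covariate the location is a
    lowess fit of e on the covariate (variance trend).
    """
    ok = (s_sq > 0) & (df > 0)
    s = np.where(ok, s_sq, 1.0)
    d = np.where(ok, df, 1.0)
    e = np.log(s) - special.digamma(d / 2.0) + np.log(d / 2.0)
    if covariate is None:
        e_loc = np.full_like(e, np.mean(e[ok]))
    else:
        fitted = lowess(
            e[ok], covariate[ok], frac=0.5, it=0, return_sorted=False
        )
        e_loc = np.empty_like(e)
        e_loc[ok] = fitted
        e_loc[~ok] = np.mean(fitted)
    resid = e - e_loc
    n_ok = int(ok.sum())
    if n_ok < 2:
        return np.inf, np.exp(e_loc)
    evar = np.sum(resid[ok] ** 2) / (n_ok - 1) - np.mean(
        special.polygamma(1, d[ok] / 2.0)
    )
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(e_loc + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(e_loc)
    return d0, s0_sq


def _design_matrix(
    pheno: pd.DataFrame, covariates: tuple[str, ...], apoe_coding: str
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(pheno))]
    names = ["intercept"]
    cols.append((pheno["diagnosis"] == "AD").to_numpy(float))
    names.append("diagnosis[AD]")
    for cov in covariates:
        if cov == "age":
            cols.append(pheno["age"].to_numpy(float))
            names.append("age")
        elif cov == "sex":
            cols.append((pheno["sex"] == "female").to_numpy(float))
            names.append("sex[female]")
        elif cov == "apoe4":
            counts = pheno["apoe4"].to_numpy(float)
            if apoe_coding == "excluded":
                continue
            if apoe_coding == "continuous":
                cols.append(counts)
                names.append("apoe4")
            elif apoe_coding == "categorical":
                for level in (1, 2):
                    cols.append((counts == level).astype(float))
                    names.append(f"apoe4[{level}]")
            else:
                raise ValueError(f"unknown apoe_coding {apoe_coding!r}")
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    return np.column_stack(cols), names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns involved in the collinearity by dropping one at a time
        collinear = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")


class ModeratedDE:
    """Covariate-adjusted moderated differential expression model.

    Parameters
    ----------
    expr
        Normalized log2 expression, features x samples.
    pheno
        Phenotype table with ``diagnosis``, ``age``, ``sex``, ``apoe4``.
    covariates
        Adjustment covariates, subset of {"age", "sex", "apoe4"}.
    apoe_coding
        "continuous" (0/1/2 count), "categorical" (two dummies), or
        "excluded".
    trend
        Model the prior variance as a lowess function of average intensity.
    robust
        Reserved flag; robust hyperparameter estimation is not implemented
        and the flag is ignored with a warning.
    sample_weights
        Optional positive per-sample weights (uniform default).
    """

    def __init__(
        self,
        expr: pd.DataFrame,
        pheno: pd.DataFrame,
        covariates: tuple[str, ...] = ("age", "sex", "apoe4"),
        apoe_coding: str = "continuous",
        trend: bool = True,
        robust: bool = False,
        sample_weights: np.ndarray | None = None,
    ) -> None:
        io.validate_phenotype(pheno)
        io.check_aligned(expr, pheno)
        self.expr = expr
        self.pheno = pheno.loc[expr.columns]
        if len(set(covariates)) != len(covariates):
            raise ValueError("duplicate covariates")
        self.covariates = tuple(covariates)
        self.apoe_coding = apoe_coding
        self.trend = bool(trend)
        if robust:
            warnings.warn(
                "robust hyperparameter estimation is not implemented; "
                "proceeding with the plain empirical-Bayes fit",
                stacklevel=2,
            )
        counts = self.pheno["diagnosis"].value_counts()
        if counts.get("AD", 0) < 2 or counts.get("control", 0) < 2:
            raise ValueError("need at least 2 samples per diagnosis group")
        if sample_weights is not None:
            sample_weights = np.asarray(sample_weights, dtype=float)
            if sample_weights.shape != (expr.shape[1],) or (sample_weights <= 0).any():
                raise ValueError("sample_weights must be positive, one per sample")
        self.sample_weights = sample_weights

    def fit(self, prior_df: float | None = None) -> "DEResults":
        """Fit per-feature OLS and apply empirical-Bayes variance moderation.

        ``prior_df`` overrides the estimated d0 (0 turns moderation off and
        reproduces the ordinary per-feature t-statistics).
        """
        X_full, names = _design_matrix(self.pheno, self.covariates, self.apoe_coding)
        _check_full_rank(X_full, names)
        Y = self.expr.to_numpy(float)
        n_feat, n_samp = Y.shape
        w = (
            np.ones(n_samp)
            if self.sample_weights is None
            else self.sample_weights.copy()
        )
        is_ad = (self.pheno["diagnosis"] == "AD").to_numpy()

        coef = np.full(n_feat, np.nan)
        unscaled_se = np.full(n_feat, np.nan)  # sqrt((X'WX)^-1 [diag,diag])
        s_sq = np.full(n_feat, np.nan)
        df_resid = np.zeros(n_feat)
        avg_expr = np.nanmean(Y, axis=1)
        kept = np.ones(n_feat, bool)

        sw = np.sqrt(w)
        complete = ~np.isnan(Y)
        full_rows = complete.all(axis=1)

        def fit_block(rows: np.ndarray, mask: np.ndarray) -> None:
            X = X_full[mask] * sw[mask, None]
            Yb = Y[np.ix_(rows, mask)] * sw[None, mask]
            n_obs = int(mask.sum())
            df = n_obs - X.shape[1]
            if df <= 0:
                kept[rows] = False
                return
            xtx_inv = np.linalg.inv(X.T @ X)
            beta = Yb @ (X @ xtx_inv)
            resid = Yb - beta @ X.T
            coef[rows] = beta[:, 1]
            unscaled_se[rows] = np.sqrt(xtx_inv[1, 1])
            s_sq[rows] = np.sum(resid**2, axis=1) / df
            df_resid[rows] = df

        if full_rows.any():
            fit_block(np.where(full_rows)[0], np.ones(n_samp, bool))
        for g in np.where(~full_rows)[0]:
            mask = complete[g]
            n_ad_ok = int((mask & is_ad).sum())
            n_ct_ok = int((mask & ~is_ad).sum())
            if n_ad_ok < MIN_COMPLETE_PER_GROUP or n_ct_ok < MIN_COMPLETE_PER_GROUP:
                kept[g] = False
                continue
            avg_expr[g] = np.nanmean(Y[g])
            fit_block(np.array([g]), mask)

        n_dropped = int((~kept).sum())
        if n_dropped:
            warnings.warn(
                f"dropping {n_dropped} feature(s) with fewer than "
                f"{MIN_COMPLETE_PER_GROUP} complete samples in a group",
                stacklevel=2,
            )
        k = np.where(kept)[0]

        covariate = avg_expr[k] if self.trend else None
        d0_est, s0_sq = _fit_f_dist(s_sq[k], df_resid[k], covariate)
        d0 = d0_est if prior_df is None else float(prior_df)
        s0_scalar = float(np.exp(np.mean(np.log(s0_sq)))) if np.ndim(s0_sq) else float(s0_sq)

        if np.isinf(d0):
            s_tilde_sq = np.broadcast_to(s0_sq, k.shape).astype(float)
            df_total = np.full(k.size, np.inf)
        elif d0 == 0:
            s_tilde_sq = s_sq[k]
            df_total = df_resid[k]
        else:
            s_tilde_sq = (d0 * s0_sq + df_resid[k] * s_sq[k]) / (d0 + df_resid[k])
            df_total = d0 + df_resid[k]
        t_mod = coef[k] / (unscaled_se[k] * np.sqrt(s_tilde_sq))
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
        q = bh_adjust(p)

        table = pd.DataFrame(
            {
                "log2fc": coef[k],
                "avg_expr": avg_expr[k],
                "t_mod": t_mod,
                "p": p,
                "q": q,
            },
            index=self.expr.index[k],
        )
        table.index.name = "feature_id"
        priors = EBPriors(
            d0=float(d0) if not np.isinf(d0) else np.inf,
            s0_sq=s0_scalar,
            s0_sq_trend=np.asarray(s0_sq) if self.trend else None,
        )
        return DEResults(
            table=table,
            priors=priors,
            s_sq=s_sq[k],
            s_tilde_sq=np.asarray(s_tilde_sq, float),
            df_resid=df_resid[k],
            model=self,
        )


@dataclass
class DEResults:
    """Per-feature moderated DE statistics plus the EB hyperparameters."""

    table: pd.DataFrame
    priors: EBPriors
    s_sq: np.ndarray
    s_tilde_sq: np.ndarray
    df_resid: np.ndarray
    model: ModeratedDE = field(repr=False, default=None)

    def significant(self, alpha: float = 0.05) -> pd.Index:
        return self.table.index[self.table["q"] < alpha]

    def summary(self, top: int = 10) -> str:
        d0 = self.priors.d0
        lines = [
            "Moderated differential expression (AD minus control)",
            f"  features: {len(self.table)}",
            f"  prior df d0: {'inf' if np.isinf(d0) else f'{d0:.2f}'}",
            f"  prior variance s0^2: {self.priors.s0_sq:.4f}"
            + (" (trended)" if self.priors.s0_sq_trend is not None else ""),
            f"  significant at q<0.05: {len(self.significant())}",
            "",
            self.table.reindex(
                self.table["p"].sort_values().index[:top]
            ).to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> str:
        self.table.to_csv(path, sep="\t")
        return str(path)


def compare_covariate_models(
    res_a: DEResults | pd.DataFrame,
    res_b: DEResults | pd.DataFrame,
    alpha: float = 0.05,
) -> ModelComparison:
    """Sensitivity comparison of two covariate-model DE results.

    Jaccard index over the q<alpha significant sets (missing, not 0, when
    both sets are empty) and Spearman correlation of log2FC over features
    present in both results.
    """
    ta = res_a.table if isinstance(res_a, DEResults) else res_a
    tb = res_b.table if isinstance(res_b, DEResults) else res_b
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both DE results must cover at least one feature")
    sig_a = set(ta.index[ta["q"] < alpha])
    sig_b = set(tb.index[tb["q"] < alpha])
    union = sig_a | sig_b
    jaccard = len(sig_a & sig_b) / len(union) if union else None
    shared = ta.index.intersection(tb.index)
    if len(shared) >= 2:
        rho = stats.spearmanr(
            ta.loc[shared, "log2fc"], tb.loc[shared, "log2fc"]
        ).statistic
    else:
        rho = np.nan
    return ModelComparison(
        jaccard=jaccard,
        spearman_log2fc=float(rho),
        n_sig_a=len(sig_a),
        n_sig_b=len(sig_b),
    )
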