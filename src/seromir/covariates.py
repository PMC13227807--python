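"""Univariate diagnostic metrics for clinical covariates and
miRNA-covariate association statistics.

Covers confusion-matrix-derived operating points with Youden thresholding,
rank-based AUC/average precision, stratified cross-validated transfer of a
training-fold Youden threshold, Cramér's V for contingency tables, and
rank-residualized partial Spearman correlations between miRNA expression
and clinical covariates (age, sex, APOE e4 allele count).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .de import bh_adjust

__all__ = [
    "ConfusionCounts",
    "OperatingPoint",
    "confusion_metrics",
    "rank_metrics",
    "youden_select",
    "crossval_univariate",
    "cramers_v",
    "partial_rank_assoc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        counts = (self.tp, self.fp, self.tn, self.fn)
        if any(c < 0 for c in counts):
            raise ValueError("confusion counts must be non-negative")
        if sum(counts) < 1:
            raise ValueError("confusion counts are all zero")


@dataclass
class OperatingPoint:
    """Threshold-level classification metrics (rule: score >= threshold => positive)."""

    threshold: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None
    youden_j: float | None


def _safe_div(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(c: ConfusionCounts) -> OperatingPoint:
    """Sensitivity/specificity/PPV/NPV/accuracy/Youden-J from raw counts.

    Metrics with a zero denominator are reported as missing.
    """
    sens = _safe_div(c.tp, c.tp + c.fn)
    spec = _safe_div(c.tn, c.tn + c.fp)
    return OperatingPoint(
        threshold=None,
        sensitivity=sens,
        specificity=spec,
        ppv=_safe_div(c.tp, c.tp + c.fp),
        npv=_safe_div(c.tn, c.tn + c.fn),
        accuracy=(c.tp + c.tn) / (c.tp + c.fp + c.tn + c.fn),
        youden_j=None if sens is None or spec is None else sens + spec - 1.0,
    )


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return y


def rank_metrics(scores, labels) -> tuple[float, float]:
    """(AUC, average precision) using raw scores as the classifier.

    AUC is the tie-aware pairwise concordance P(score_pos > score_neg) +
    0.5*P(tie); AP is the rank-based step sum of precision at each positive.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, float)
    return float(roc_auc_score(y, s)), float(average_precision_score(y, s))


def _threshold_candidates(scores: np.ndarray) -> np.ndarray:
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.r_[-np.inf, mids, np.inf]


def youden_select(scores, labels) -> OperatingPoint:
    """Operating point maximizing Youden's J over midpoint thresholds.

    Candidates are midpoints between adjacent distinct scores plus +/-inf;
    ties in J are broken toward the lowest threshold.  Classification rule:
    score >= threshold => positive.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, float)
    best = None
    for thr in _threshold_candidates(s):
        pred = s >= thr
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        tn = int(np.sum(~pred & (y == 0)))
        fn = int(np.sum(~pred & (y == 1)))
        op = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
        op.threshold = float(thr)
        if best is None or op.youden_j > best.youden_j + 1e-12:
            best = op
    return best


def crossval_univariate(
    scores, labels, k: int = 5, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified k-fold univariate logistic evaluation with Youden transfer.

    Per fold: fit a univariate logistic model on the training split, select
    the Youden threshold on the training predictions, then apply it
    unchanged to the validation predictions.  Returns (per-fold table,
    mean +/- SD summary).  Deterministic given ``seed``.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, float).reshape(-1, 1)
    if min(np.bincount(y)) < k:
        raise ValueError(
            f"each class needs at least k={k} members; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, va) in enumerate(skf.split(s, y)):
        model = LogisticRegression(max_iter=1000)
        model.fit(s[tr], y[tr])
        p_tr = model.predict_proba(s[tr])[:, 1]
        p_va = model.predict_proba(s[va])[:, 1]
        op_tr = youden_select(p_tr, y[tr])
        pred = p_va >= op_tr.threshold
        tp = int(np.sum(pred & (y[va] == 1)))
        fp = int(np.sum(pred & (y[va] == 0)))
        tn = int(np.sum(~pred & (y[va] == 0)))
        fn = int(np.sum(~pred & (y[va] == 1)))
        op = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
        auc, ap = rank_metrics(p_va, y[va])
        rows.append(
            {
                "fold": fold,
                "threshold": op_tr.threshold,
                "sensitivity": op.sensitivity,
                "specificity": op.specificity,
                "ppv": op.ppv,
                "npv": op.npv,
                "accuracy": op.accuracy,
                "auc": auc,
                "ap": ap,
            }
        )
    per_fold = pd.DataFrame(rows).set_index("fold")
    summary = pd.DataFrame({"mean": per_fold.mean(), "sd": per_fold.std(ddof=1)})
    return per_fold, summary


def cramers_v(table) -> tuple[float, float]:
    """(chi-square, Cramér's V) for an r x c contingency table.

    Pearson chi-square without continuity correction;
    V = sqrt(chi2 / (n * min(r-1, c-1))).
    """
    t = np.asarray(table, float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (t < 0).any() or t.sum() < 1:
        raise ValueError("counts must be non-negative with a positive total")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal row/column in contingency table")
    chi2 = stats.chi2_contingency(t, correction=False).statistic
    v = np.sqrt(chi2 / (t.sum() * (min(t.shape) - 1)))
    return float(chi2), float(v)


def _covariate_vector(pheno: pd.DataFrame, name: str) -> np.ndarray:
    if name == "sex":
        return (pheno["sex"] == "female").to_numpy(float)
    return pheno[name].to_numpy(float)


def partial_rank_assoc(
    expr: pd.DataFrame,
    pheno: pd.DataFrame,
    target: str,
    adjust_for: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Partial Spearman correlation of every miRNA with a clinical covariate.

    All variables are rank-transformed (ties averaged); the miRNA and the
    target are then OLS-residualized on the adjusters plus an intercept, and
    the coefficient is the Pearson correlation of the residuals with a
    t-approximation p-value on n - 2 - #adjusters df.  With no adjusters
    this reduces exactly to plain Spearman rho (and, for a binary target,
    to the rank point-biserial correlation).  q-values are BH-adjusted
    across features.  Constant features get a missing coefficient.
    """
    pheno = pheno.loc[expr.columns]
    cols = list(dict.fromkeys([target, *adjust_for]))
    complete = pheno[cols].notna().all(axis=1)
    t_raw = _covariate_vector(pheno, target)
    Z_raw = np.column_stack(
        [_covariate_vector(pheno, a) for a in adjust_for]
    ) if adjust_for else np.empty((len(pheno), 0))

    rows = []
    pvals = []
    for fid, row in expr.iterrows():
        x_raw = row.to_numpy(float)
        ok = complete.to_numpy() & ~np.isnan(x_raw) & ~np.isnan(t_raw)
        n = int(ok.sum())
        df = n - 2 - len(adjust_for)
        if n < 10 or df < 1:
            raise ValueError(f"feature {fid!r}: fewer than 10 complete samples")
        x = stats.rankdata(x_raw[ok])
        t = stats.rankdata(t_raw[ok])
        if np.ptp(x) == 0 or np.ptp(t) == 0:
            rows.append((fid, np.nan, np.nan))
            pvals.append(np.nan)
            continue
        if adjust_for:
            Z = np.column_stack(
                [np.ones(n)] + [stats.rankdata(Z_raw[ok, j]) for j in range(Z_raw.shape[1])]
            )
            hat = Z @ np.linalg.pinv(Z)
            x = x - hat @ x
            t = t - hat @ t
        else:
            x = x - x.mean()
            t = t - t.mean()
        denom = np.sqrt(np.sum(x**2) * np.sum(t**2))
        r = float(np.sum(x * t) / denom) if denom > 0 else np.nan
        if np.isnan(r):
            p = np.nan
        else:
            r_c = np.clip(r, -1 + 1e-15, 1 - 1e-15)
            t_stat = r_c * np.sqrt(df / (1 - r_c**2))
            p = 2.0 * stats.t.sf(abs(t_stat), df)
        rows.append((fid, r, p))
        pvals.append(p)

    out = pd.DataFrame(rows, columns=["feature_id", "coefficient", "p"]).set_index(
        "feature_id"
    )
    out["covariate"] = target
    p_arr = out["p"].to_numpy()
    valid = ~np.isnan(p_arr)
    q = np.full(len(out), np.nan)
    if valid.any():
        q[valid] = bh_adjust(p_arr[valid])
    out["q"] = q
    if (~valid).any():
        warnings.warn(
            f"{int((~valid).sum())} constant feature(s) reported with missing "
            "coefficient",
            stacklevel=2,
        )
    return out[["covariate", "coefficient", "p", "q"]]
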