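"""Directionality statistics and the +/-1-weighted candidate signature score.

Candidate miRNAs are split by the sign of their reported correlation with
MMSE cognitive scores.  Positively correlated miRNAs are expected to be
downregulated in AD and negatively correlated ones upregulated, so the
per-sample signature score weights z-scored expression of the negative set
+1 and the positive set -1 (higher score = more AD-like profile).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .de import DEResults, bh_adjust

__all__ = [
    "CandidateSet",
    "DirectionReport",
    "assess_direction",
    "mean_rank_set_test",
    "signed_shift_tests",
    "compute_signature_score",
    "test_signature_association",
    "direction_report",
]


@dataclass(frozen=True)
class CandidateSet:
    """A direction-annotated candidate miRNA set.

    ``direction`` is the sign of the reported correlation with MMSE;
    ``expanded_flags`` marks members added by family/arm expansion.
    """

    members: tuple[str, ...]
    direction: str  # {"positive", "negative"}
    expanded_flags: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if self.direction not in ("positive", "negative"):
            raise ValueError("direction must be 'positive' or 'negative'")
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate members in candidate set")
        if self.expanded_flags and len(self.expanded_flags) != len(self.members):
            raise ValueError("expanded_flags length mismatch")

    @property
    def expected_sign(self) -> int:
        """Expected sign of log2FC (AD minus control) under the hypothesis:
        positive-set members down in AD (-1), negative-set members up (+1)."""
        return -1 if self.direction == "positive" else +1


@dataclass
class DirectionReport:
    """Per-member consistency plus set-level directional-bias tests."""

    consistency: pd.DataFrame  # feature_id, log2fc, q, consistent
    absent: tuple[str, ...]
    n_consistent: int
    mean_rank_p: float
    sign_test_p: float | None
    signed_rank_p: float | None


def _get_table(de: DEResults | pd.DataFrame) -> pd.DataFrame:
    return de.table if isinstance(de, DEResults) else de


def assess_direction(
    de: DEResults | pd.DataFrame, cset: CandidateSet, alpha: float = 0.05
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Flag each set member as directionally consistent or not.

    A member is consistent iff q < alpha AND sign(log2fc) matches the
    expected direction.  Members absent from the DE table are listed
    separately, not errored.
    """
    table = _get_table(de)
    present = [m for m in cset.members if m in table.index]
    absent = tuple(m for m in cset.members if m not in table.index)
    sub = table.loc[present, ["log2fc", "q"]].copy()
    sub["consistent"] = (sub["q"] < alpha) & (
        np.sign(sub["log2fc"]) == cset.expected_sign
    )
    sub.index.name = "feature_id"
    return sub, absent


def mean_rank_set_test(
    statistics: pd.Series | np.ndarray,
    members,
    alternative: str = "greater",
) -> float:
    """Mean-rank gene-set test: Wilcoxon rank-sum of set vs complement.

    Ranks the statistic over ALL retained features, compares the set's rank
    sum against its null under random assignment using the normal
    approximation with tie correction (no continuity correction, so the
    'greater' and 'less' p-values sum to exactly 1 when there are no ties).
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if isinstance(statistics, pd.Series):
        members = list(members)
        missing = set(members) - set(statistics.index)
        if missing:
            raise KeyError(f"set members absent from statistics: {sorted(missing)[:5]}")
        in_set = statistics.index.isin(members)
        values = statistics.to_numpy(float)
    else:
        values = np.asarray(statistics, float)
        in_set = np.zeros(values.size, bool)
        in_set[np.asarray(list(members), int)] = True
    n = values.size
    m = int(in_set.sum())
    if m < 1 or m >= n:
        raise ValueError("set must be a non-empty proper subset of the features")
    ranks = stats.rankdata(values, method="average")
    r_set = float(ranks[in_set].sum())
    mu = m * (n + 1) / 2.0
    # tie-corrected variance of the rank sum
    _, counts = np.unique(values, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = m * (n - m) / 12.0 * (n + 1 - tie_term)
    if var <= 0:  # all values identical
        return 0.5
    z = (r_set - mu) / np.sqrt(var)
    return float(stats.norm.sf(z) if alternative == "greater" else stats.norm.cdf(z))


def signed_shift_tests(
    log2fc, expected_sign: int
) -> tuple[float | None, float | None]:
    """One-tailed sign test and one-sided Wilcoxon signed-rank test that the
    log2FC values of a set shift in the expected direction.

    The sign test drops exact zeros and is the exact binomial tail on the
    count of values matching the expected sign.  The signed-rank test is
    exact for n <= 25 and uses the normal approximation with continuity
    correction otherwise.  Returns (None, None) when all values are zero.
    """
    if expected_sign not in (-1, 1):
        raise ValueError("expected_sign must be +1 or -1")
    x = np.asarray(log2fc, float) * expected_sign
    nonzero = x[x != 0]
    if nonzero.size == 0:
        warnings.warn("all log2FC values are zero; shift tests undefined", stacklevel=2)
        return None, None
    k = int((nonzero > 0).sum())
    sign_p = float(stats.binomtest(k, nonzero.size, 0.5, alternative="greater").pvalue)
    if nonzero.size >= 5:
        try:
            wil = stats.wilcoxon(
                nonzero,
                alternative="greater",
                method="exact" if nonzero.size <= 25 else "approx",
                correction=nonzero.size > 25,
            )
            signed_rank_p = float(wil.pvalue)
        except ValueError:
            signed_rank_p = None
    else:
        signed_rank_p = None
    return sign_p, signed_rank_p


def compute_signature_score(
    expr: pd.DataFrame,
    positive: CandidateSet,
    negative: CandidateSet,
) -> pd.Series:
    """Per-sample signature score from row-z-scored candidate expression.

    score_s = mean over negative-set z-values - mean over positive-set
    z-values.  Each feature is z-scored across all samples (so the score is
    computable without diagnosis labels and is invariant to per-feature
    affine rescaling); zero-SD or absent features are excluded with a
    warning.  Missing cells are ignored per sample via nan-mean.
    """

    def usable(cset: CandidateSet) -> list[str]:
        present = [m for m in cset.members if m in expr.index]
        absent = set(cset.members) - set(present)
        keep = []
        degenerate = []
        for m in present:
            sd = expr.loc[m].std(ddof=1)
            if np.isfinite(sd) and sd > 0:
                keep.append(m)
            else:
                degenerate.append(m)
        if absent or degenerate:
            warnings.warn(
                f"{cset.direction} set: skipping {sorted(absent)} (absent) "
                f"and {degenerate} (zero/undefined SD)",
                stacklevel=3,
            )
        return keep

    pos, neg = usable(positive), usable(negative)
    if not pos and not neg:
        raise ValueError("no usable candidate features in either set")

    def z_block(members: list[str]) -> np.ndarray:
        block = expr.loc[members].to_numpy(float)
        mu = np.nanmean(block, axis=1, keepdims=True)
        sd = np.nanstd(block, axis=1, ddof=1, keepdims=True)
        return (block - mu) / sd

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        neg_part = np.nanmean(z_block(neg), axis=0) if neg else 0.0
        pos_part = np.nanmean(z_block(pos), axis=0) if pos else 0.0
    score = pd.Series(neg_part - pos_part, index=expr.columns, name="signature_score")
    return score


def test_signature_association(
    score: pd.Series, pheno: pd.DataFrame
) -> dict[str, float]:
    """OLS of the signature score on diagnosis + age + sex + APOE e4 count.

    Returns the adjusted diagnosis (AD vs control) coefficient, its standard
    error and two-sided p-value.
    """
    pheno = pheno.loc[score.index]
    X = pd.DataFrame(
        {
            "diagnosis_ad": (pheno["diagnosis"] == "AD").astype(float),
            "age": pheno["age"].astype(float),
            "sex_female": (pheno["sex"] == "female").astype(float),
            "apoe4": pheno["apoe4"].astype(float),
        }
    )
    X.insert(0, "const", 1.0)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear design in signature association model")
    fit = sm.OLS(score.to_numpy(float), X).fit()
    return {
        "coef": float(fit.params["diagnosis_ad"]),
        "se": float(fit.bse["diagnosis_ad"]),
        "p": float(fit.pvalues["diagnosis_ad"]),
    }


def direction_report(
    de: DEResults | pd.DataFrame,
    cset: CandidateSet,
    alpha: float = 0.05,
    statistic: str = "auto",
) -> DirectionReport:
    """Full directional-bias assessment for one candidate set.

    The mean-rank test prefers the moderated t-statistic and falls back to
    log2FC when t is unavailable; the one-sided alternative follows the
    set's expected direction.
    """
    table = _get_table(de)
    consistency, absent = assess_direction(de, cset, alpha)
    col = (
        "t_mod"
        if statistic == "auto" and "t_mod" in table.columns
        else ("log2fc" if statistic == "auto" else statistic)
    )
    members = [m for m in cset.members if m in table.index]
    alternative = "greater" if cset.expected_sign > 0 else "less"
    mean_rank_p = mean_rank_set_test(table[col], members, alternative)
    sign_p, signed_rank_p = signed_shift_tests(
        table.loc[members, "log2fc"].to_numpy(), cset.expected_sign
    )
    return DirectionReport(
        consistency=consistency,
        absent=absent,
        n_consistent=int(consistency["consistent"].sum()),
        mean_rank_p=mean_rank_p,
        sign_test_p=sign_p,
        signed_rank_p=signed_rank_p,
    )
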