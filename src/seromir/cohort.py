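"""Seeded synthetic serum-miRNA cohorts.

The generator emulates the structure of a large AD serum microarray cohort:
a strongly age-imbalanced case/control design (AD median age ~80 vs ~71),
a female-skewed AD group, APOE e4 enrichment in AD, ~2,500 background
miRNA features containing a literature-derived candidate set split into
"positively correlated" and "negatively correlated" subsets (sign of the
reported correlation with MMSE), block-correlated feature clusters driven
by shared latent factors, and configurable group effects on the log2 scale.

Confounding between covariates and diagnosis is induced purely by per-group
sampling parameters (observational imbalance), not by a structural model.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import io

__all__ = [
    "CohortConfig",
    "gse120584_like_config",
    "generate_cohort",
    "write_dataset",
    "POSITIVE_CANDIDATES",
    "NEGATIVE_CANDIDATES",
    "LARGE_CLUSTER_MEMBERS",
]

# Literature-derived candidate miRNAs after family/arm expansion: 20 whose
# serum level correlates positively with MMSE and 12 correlating negatively.
POSITIVE_CANDIDATES: tuple[str, ...] = (
    "miR-133b",
    "miR-137",
    "miR-148a-3p",
    "miR-193a-3p",
    "miR-27a-3p",
    "miR-320a",
    "miR-331-3p",
    "miR-340-5p",
    "miR-511-3p",
    "miR-342-3p",
    "miR-202-5p",
    "miR-202-3p",
    "miR-211-5p",
    "miR-211-3p",
    "miR-222-3p",
    "miR-222-5p",
    "miR-223-3p",
    "miR-223-5p",
    "miR-26b-5p",
    "miR-26b-3p",
)
NEGATIVE_CANDIDATES: tuple[str, ...] = (
    "miR-24-3p",
    "miR-28-3p",
    "miR-98-5p",
    "miR-142-5p",
    "miR-128-3p",
    "miR-128-1-5p",
    "miR-128-2-5p",
    "miR-138-5p",
    "miR-138-2-3p",
    "miR-138-1-3p",
    "miR-9-5p",
    "miR-9-3p",
)

# Default planted correlation block: the 18 candidates that form the largest
# connected component of the empirical |rho|>=0.80 correlation network.
LARGE_CLUSTER_MEMBERS: tuple[str, ...] = (
    "miR-128-3p",
    "miR-137",
    "miR-138-2-3p",
    "miR-142-5p",
    "miR-148a-3p",
    "miR-193a-3p",
    "miR-202-3p",
    "miR-202-5p",
    "miR-222-3p",
    "miR-223-5p",
    "miR-26b-5p",
    "miR-27a-3p",
    "miR-28-3p",
    "miR-340-5p",
    "miR-511-3p",
    "miR-9-3p",
    "miR-9-5p",
    "miR-98-5p",
)

AGE_BOUNDS = (55.0, 95.0)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort; defaults emulate the study cohort."""

    n_ad: int = 1021
    n_control: int = 288
    n_features: int = 2500
    candidate_positive: tuple[str, ...] = POSITIVE_CANDIDATES
    candidate_negative: tuple[str, ...] = NEGATIVE_CANDIDATES
    #: (location, scale) of the truncated-normal age draw, per group (years)
    age_params: dict = field(
        default_factory=lambda: {"AD": (80.0, 5.9), "control": (71.0, 6.7)}
    )
    female_prob: dict = field(
        default_factory=lambda: {"AD": 714 / 1021, "control": 137 / 288}
    )
    apoe_probs: dict = field(
        default_factory=lambda: {
            "AD": (577 / 1021, 376 / 1021, 68 / 1021),
            "control": (238 / 288, 46 / 288, 4 / 288),
        }
    )
    #: list of (member feature IDs, within-cluster Spearman rho target)
    cluster_spec: tuple = ((LARGE_CLUSTER_MEMBERS, 0.85),)
    #: feature ID -> true log2 fold change (AD minus control)
    effect_sizes: dict = field(
        default_factory=lambda: {
            **{m: -0.3 for m in POSITIVE_CANDIDATES},
            **{m: +0.3 for m in NEGATIVE_CANDIDATES},
        }
    )
    noise_sd: float = 1.0  # residual SD of named features, log2 units
    #: background features draw their residual SD uniformly from this range,
    #: emulating the spread from near-noise-floor probes to highly variable
    #: ones that makes the row-SD variance filter meaningful
    background_sd_range: tuple[float, float] = (0.4, 1.6)
    missing_rate: float = 0.0  # MCAR missingness fraction
    baseline_range: tuple[float, float] = (6.0, 14.0)  # mean log2 intensity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ad < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per group")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.background_sd_range
        if not 0 < lo <= hi:
            raise ValueError("background_sd_range must satisfy 0 < low <= high")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        pos, neg = set(self.candidate_positive), set(self.candidate_negative)
        if len(pos) != len(self.candidate_positive) or len(neg) != len(
            self.candidate_negative
        ):
            raise ValueError("duplicate feature IDs within a candidate set")
        if pos & neg:
            raise ValueError(f"candidate sets overlap: {sorted(pos & neg)[:5]}")
        if len(pos) + len(neg) > self.n_features:
            raise ValueError("n_features smaller than the candidate sets")
        for group in ("AD", "control"):
            p = self.female_prob[group]
            if not 0 <= p <= 1:
                raise ValueError(f"female_prob[{group}]={p} outside [0, 1]")
            probs = np.asarray(self.apoe_probs[group], dtype=float)
            if probs.shape != (3,) or (probs < 0).any() or (probs > 1).any():
                raise ValueError(f"apoe_probs[{group}] must be a probability 3-vector")
            if abs(probs.sum() - 1.0) > 1e-8:
                raise ValueError(f"apoe_probs[{group}] must sum to 1")
        known = pos | neg
        for members, rho in self.cluster_spec:
            if not 0 < rho < 1:
                raise ValueError(f"cluster rho target {rho} outside (0, 1)")
            extra = set(members) - known
            # cluster members outside the candidate sets must still be
            # nameable features; they are appended before background fill
            known |= extra

    def feature_ids(self) -> list[str]:
        """Deterministic feature ordering: candidates, extra cluster members,
        then synthetic background features padded to ``n_features``."""
        ids = list(self.candidate_positive) + list(self.candidate_negative)
        seen = set(ids)
        for members, _ in self.cluster_spec:
            for m in members:
                if m not in seen:
                    ids.append(m)
                    seen.add(m)
        for m in self.effect_sizes:
            if m not in seen:
                ids.append(m)
                seen.add(m)
        if len(ids) > self.n_features:
            raise ValueError("n_features smaller than named features")
        n_bg = self.n_features - len(ids)
        ids.extend(f"miR-sim-{i:04d}" for i in range(n_bg))
        return ids


def gse120584_like_config(**overrides) -> CohortConfig:
    """The default study-like configuration with selected fields overridden."""
    return dataclasses.replace(CohortConfig(), **overrides)


def _truncnorm(rng: np.random.Generator, loc: float, scale: float, size: int):
    a, b = (AGE_BOUNDS[0] - loc) / scale, (AGE_BOUNDS[1] - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cohort: (expression matrix features x samples, phenotype table).

    Deterministic given ``config.seed``.  Group effects enter as exact mean
    shifts (the configured log2FC) before noise; cluster members share a
    per-cluster Gaussian latent factor whose loading is chosen analytically
    so the realized within-cluster Spearman rho approaches the target
    (Pearson loading ``2*sin(pi*rho_s/6)``, the Gaussian rank-correlation map).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_ad + config.n_control
    sample_ids = [f"AD_{i + 1:04d}" for i in range(config.n_ad)] + [
        f"CT_{i + 1:04d}" for i in range(config.n_control)
    ]
    is_ad = np.r_[np.ones(config.n_ad, bool), np.zeros(config.n_control, bool)]

    age = np.empty(n)
    sex = np.empty(n, object)
    apoe = np.empty(n, int)
    for group, mask in (("AD", is_ad), ("control", ~is_ad)):
        m = int(mask.sum())
        loc, scale = config.age_params[group]
        age[mask] = _truncnorm(rng, loc, scale, m)
        sex[mask] = np.where(
            rng.random(m) < config.female_prob[group], "female", "male"
        )
        apoe[mask] = rng.choice(3, size=m, p=np.asarray(config.apoe_probs[group]))
    pheno = pd.DataFrame(
        {
            "diagnosis": np.where(is_ad, "AD", "control"),
            "age": age,
            "sex": sex,
            "apoe4": apoe,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    feature_ids = config.feature_ids()
    p = len(feature_ids)
    idx = {f: i for i, f in enumerate(feature_ids)}
    baseline = rng.uniform(*config.baseline_range, size=p)

    # residual structure: shared latent factor per cluster + independent noise
    loading = np.zeros(p)
    latent = np.zeros((p, n))
    for members, rho_target in config.cluster_spec:
        lam = 2.0 * np.sin(np.pi * rho_target / 6.0)  # Pearson giving Spearman~rho
        z = rng.standard_normal(n)
        for m in members:
            loading[idx[m]] = np.sqrt(lam)
            latent[idx[m]] = z
    eps = rng.standard_normal((p, n))
    resid = loading[:, None] * latent + np.sqrt(1.0 - loading**2)[:, None] * eps

    effects = np.zeros(p)
    for f, fc in config.effect_sizes.items():
        effects[idx[f]] = fc
    # named features use noise_sd exactly; background probes span a range of
    # residual SDs so row-SD filtering separates flat from variable features
    sd = np.full(p, config.noise_sd)
    background = np.array([f.startswith("miR-sim-") for f in feature_ids])
    sd[background] = rng.uniform(*config.background_sd_range, size=int(background.sum()))
    values = (
        baseline[:, None]
        + effects[:, None] * is_ad[None, :].astype(float)
        + sd[:, None] * resid
    )
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = np.where(mask, np.nan, values)

    expr = pd.DataFrame(
        values, index=pd.Index(feature_ids, name="feature_id"), columns=sample_ids
    )
    return expr, pheno


def write_dataset(
    expr: pd.DataFrame, pheno: pd.DataFrame, directory: str | os.PathLike
) -> dict[str, str]:
    """Write the matrix and phenotype table as TSV; returns the file paths."""
    os.makedirs(directory, exist_ok=True)
    paths = {
        "expression": io.write_expression(
            expr, os.path.join(directory, "expression.tsv")
        ),
        "phenotype": io.write_phenotype(
            pheno, os.path.join(directory, "phenotype.tsv")
        ),
    }
    return paths
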