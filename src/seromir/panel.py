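"""Cluster-constrained miRNA panel selection inside nested cross-validation.

Within each outer training fold, candidate miRNAs are added greedily to a
clinical baseline model by forward gain — the increase in inner-CV AUC from
adding the candidate.  A minimum gain of delta AUC >= 0.005 is required;
candidates from a cluster that already contributed a member face a stricter
gate of delta AUC >= 0.010 (the one-representative-per-cluster rule admits a
second member only through that stricter gate, or replaces the first when
``within_cluster_mode="replace"``).  Selections are deduplicated per
outer-fold x repeat run unit, aggregated into a selection-frequency panel
(cluster-deduplicated), and the panel is sized by evaluating the K-AUC path
and applying the strict 1-SE rule: the smallest K whose cross-validated AUC
reaches max-AUC minus one standard error of the best K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import io
from .models import ModelSpec, _make_classifier
from .network import ClusterMap

__all__ = [
    "SelectionConfig",
    "FrequencyPanel",
    "PanelPath",
    "forward_select_fold",
    "aggregate_panel",
    "select_k_one_se",
    "PanelSelector",
    "PanelSelectionResults",
]


@dataclass(frozen=True)
class SelectionConfig:
    outer_folds: int = 5
    repeats: int = 4
    inner_folds: int = 5
    delta_min: float = 0.005
    delta_within_cluster: float = 0.010
    baseline: tuple[str, ...] = ("age", "sex")
    within_cluster_mode: str = "additional"  # or "replace"
    # fixed elastic-net penalty used for inner scoring during the greedy loop
    # (full hyperparameter tuning happens only in final evaluation)
    strength: float = 0.1
    l1_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.delta_within_cluster >= self.delta_min > 0:
            raise ValueError("need delta_within_cluster >= delta_min > 0")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.within_cluster_mode not in ("additional", "replace"):
            raise ValueError("within_cluster_mode must be 'additional' or 'replace'")


@dataclass
class FrequencyPanel:
    """Selection counts per feature after run-unit and cluster deduplication."""

    table: pd.DataFrame  # columns: count, n_runs; ordered by count desc
    dedup_level: str = "outer-fold x repeat, then cluster"

    @property
    def members(self) -> list[str]:
        return list(self.table.index)


@dataclass
class PanelPath:
    """K-AUC path with the 1-SE threshold and the selected panel size."""

    table: pd.DataFrame  # index: label, columns: k, members, auc, fold_sd
    one_se_threshold: float
    selected_k: int

    @property
    def selected_members(self) -> tuple[str, ...]:
        rows = self.table[self.table["k"] == self.selected_k]
        return tuple(rows.iloc[0]["members"])


def _inner_cv_auc(
    X: np.ndarray, y: np.ndarray, config: SelectionConfig, seed: int
) -> float:
    """Mean stratified inner-CV AUC of the fixed-penalty logistic pipeline."""
    spec = ModelSpec(name="inner", features=("f",), classifier="penalized_logistic")
    pipe, _ = _make_classifier(spec, seed)
    pipe.set_params(clf__C=1.0 / config.strength, clf__l1_ratio=config.l1_ratio)
    cv = StratifiedKFold(n_splits=config.inner_folds, shuffle=True, random_state=seed)
    aucs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tr, te in cv.split(X, y):
            pipe.fit(X[tr], y[tr])
            aucs.append(roc_auc_score(y[te], pipe.predict_proba(X[te])[:, 1]))
    return float(np.mean(aucs))


def _assemble(
    expr: pd.DataFrame, pheno: pd.DataFrame, baseline: tuple[str, ...], features
) -> np.ndarray:
    cols = []
    if "age" in baseline:
        cols.append(pheno["age"].to_numpy(float))
    if "sex" in baseline:
        cols.append((pheno["sex"] == "female").to_numpy(float))
    for f in features:
        cols.append(expr.loc[f].to_numpy(float))
    if not cols:
        cols.append(np.ones(len(pheno)))  # intercept-only baseline
    return np.column_stack(cols)


def univariate_cv_auc(
    expr: pd.DataFrame,
    pheno: pd.DataFrame,
    features=None,
    k: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Five-fold cross-validated AUC of each miRNA alone (logistic model)."""
    features = list(expr.index) if features is None else list(features)
    y = (pheno.loc[expr.columns, "diagnosis"] == "AD").to_numpy(int)
    config = SelectionConfig(inner_folds=k, seed=seed)
    out = {}
    for f in features:
        X = expr.loc[[f]].T.to_numpy(float)
        out[f] = _inner_cv_auc(X, y, config, seed)
    return pd.Series(out, name="cv_auc").sort_values(ascending=False)


def forward_select_fold(
    train_expr: pd.DataFrame,
    train_pheno: pd.DataFrame,
    clusters: ClusterMap,
    config: SelectionConfig,
    candidates=None,
    seed: int | None = None,
    univariate_auc: pd.Series | None = None,
) -> list[str]:
    """Greedy forward selection on one training fold.

    At each step every remaining candidate's inner-CV AUC gain over the
    current model (baseline covariates + selected miRNAs) is evaluated; the
    best candidate is accepted iff its gain clears the applicable gate.
    Ties break by higher gain, then higher univariate CV-AUC, then
    lexicographic feature ID.  Deterministic given the seed.
    """
    seed = config.seed if seed is None else seed
    candidates = list(train_expr.index) if candidates is None else list(candidates)
    if not candidates:
        return []
    y = (train_pheno.loc[train_expr.columns, "diagnosis"] == "AD").to_numpy(int)
    if univariate_auc is None:
        univariate_auc = univariate_cv_auc(
            train_expr, train_pheno, candidates, k=config.inner_folds, seed=seed
        )

    selected: list[str] = []
    current_auc = _inner_cv_auc(
        _assemble(train_expr, train_pheno, config.baseline, []), y, config, seed
    )
    remaining = set(candidates)
    while remaining:
        scored = []
        sel_clusters = {clusters.cluster_of(f) for f in selected}
        for cand in sorted(remaining):
            gate = (
                config.delta_within_cluster
                if clusters.cluster_of(cand) in sel_clusters
                else config.delta_min
            )
            X = _assemble(train_expr, train_pheno, config.baseline, selected + [cand])
            gain = _inner_cv_auc(X, y, config, seed) - current_auc
            if gain >= gate:
                scored.append((gain, float(univariate_auc.get(cand, 0.5)), cand))
        if not scored:
            break
        scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
        gain, _, best = scored[0]
        if (
            config.within_cluster_mode == "replace"
            and clusters.cluster_of(best) in sel_clusters
        ):
            selected = [
                f for f in selected
                if clusters.cluster_of(f) != clusters.cluster_of(best)
            ]
            X = _assemble(train_expr, train_pheno, config.baseline, selected + [best])
            gain = _inner_cv_auc(X, y, config, seed) - current_auc
        selected.append(best)
        current_auc += gain
        remaining.discard(best)
    return selected


def aggregate_panel(
    selections: list[list[str]],
    clusters: ClusterMap,
    univariate_auc: pd.Series | None = None,
) -> FrequencyPanel:
    """Aggregate per-run selections into a cluster-deduplicated frequency panel.

    Within each run unit a feature counts at most once; counts are summed
    across run units; then only the highest-frequency member per cluster
    survives (ties break by higher univariate CV-AUC, then lexicographic).
    """
    if not selections:
        raise ValueError("need at least one selection run")
    n_runs = len(selections)
    counts: dict[str, int] = {}
    for run in selections:
        for f in set(run):  # run-unit deduplication
            counts[f] = counts.get(f, 0) + 1
    if not counts:
        table = pd.DataFrame(columns=["count", "n_runs"]).rename_axis("feature_id")
        return FrequencyPanel(table=table)

    def sort_key(f: str):
        ua = float(univariate_auc.get(f, 0.5)) if univariate_auc is not None else 0.5
        return (-counts[f], -ua, f)

    survivors: dict[str | None, str] = {}
    for f in sorted(counts, key=sort_key):
        cl = clusters.cluster_of(f)
        key = cl if cl is not None else f"__singleton__{f}"
        survivors.setdefault(key, f)
    keep = sorted(survivors.values(), key=sort_key)
    table = pd.DataFrame(
        {"count": [counts[f] for f in keep], "n_runs": n_runs},
        index=pd.Index(keep, name="feature_id"),
    )
    return FrequencyPanel(table=table)


def select_k_one_se(
    path: pd.DataFrame,
    n_folds: int = 5,
    se: float | None = None,
) -> PanelPath:
    """Apply the strict 1-SE rule to a K-AUC path.

    ``path`` needs columns ``k`` and ``auc`` (optionally ``fold_sd`` and
    ``members``).  The threshold is the best AUC minus the standard error of
    the best K (fold SD / sqrt(n_folds), or an explicit ``se``); the
    selected K is the smallest panel size with AUC at or above the
    threshold.
    """
    path = path.copy()
    required = {"k", "auc"}
    if not required <= set(path.columns):
        raise ValueError("path needs 'k' and 'auc' columns")
    if (path["k"] == 0).sum() == 0:
        raise ValueError("path must include the K=0 baseline row")
    best_idx = path["auc"].idxmax()
    if se is None:
        if "fold_sd" not in path.columns:
            raise ValueError("provide fold_sd column or an explicit se")
        se = float(path.loc[best_idx, "fold_sd"]) / np.sqrt(n_folds)
    threshold = float(path.loc[best_idx, "auc"]) - se
    ok = path[path["auc"] >= threshold - 1e-12]
    selected_k = int(ok["k"].min())
    if "members" not in path.columns:
        path["members"] = [() for _ in range(len(path))]
    return PanelPath(table=path, one_se_threshold=threshold, selected_k=selected_k)


class PanelSelector:
    """Nested-CV panel selection model.

    Runs forward selection on every outer-fold x repeat training split,
    aggregates selection frequencies, evaluates the K-AUC path of the
    frequency-ranked panel, and applies the 1-SE rule.
    """

    def __init__(
        self,
        expr: pd.DataFrame,
        pheno: pd.DataFrame,
        clusters: ClusterMap,
        config: SelectionConfig = SelectionConfig(),
        candidates=None,
    ) -> None:
        io.validate_phenotype(pheno)
        io.check_aligned(expr, pheno)
        self.expr = expr
        self.pheno = pheno.loc[expr.columns]
        self.clusters = clusters
        self.config = config
        self.candidates = (
            list(expr.index) if candidates is None else list(candidates)
        )

    def fit(self) -> "PanelSelectionResults":
        cfg = self.config
        y = (self.pheno["diagnosis"] == "AD").to_numpy(int)
        X_cols = self.expr.columns.to_numpy()
        univ = univariate_cv_auc(
            self.expr.loc[self.candidates],
            self.pheno,
            k=cfg.inner_folds,
            seed=cfg.seed,
        )
        selections: list[list[str]] = []
        for rep in range(cfg.repeats):
            cv = StratifiedKFold(
                n_splits=cfg.outer_folds, shuffle=True, random_state=cfg.seed + 1000 * rep
            )
            for fold, (tr, _) in enumerate(cv.split(X_cols, y)):
                cols = X_cols[tr]
                sel = forward_select_fold(
                    self.expr.loc[self.candidates, cols],
                    self.pheno.loc[cols],
                    self.clusters,
                    cfg,
                    candidates=self.candidates,
                    seed=cfg.seed + 1000 * rep + fold,
                    univariate_auc=univ,
                )
                selections.append(sel)
        panel = aggregate_panel(selections, self.clusters, univ)
        path = self._k_auc_path(panel.members)
        panel_path = select_k_one_se(path, n_folds=cfg.outer_folds)
        return PanelSelectionResults(
            frequency_panel=panel,
            path=panel_path,
            selections=selections,
            univariate_auc=univ,
            config=cfg,
        )

    def _k_auc_path(self, ranked: list[str]) -> pd.DataFrame:
        cfg = self.config
        y = (self.pheno["diagnosis"] == "AD").to_numpy(int)
        rows = []
        for k in range(len(ranked) + 1):
            members = tuple(ranked[:k])
            X = _assemble(self.expr, self.pheno, cfg.baseline, members)
            cv = StratifiedKFold(
                n_splits=cfg.outer_folds, shuffle=True, random_state=cfg.seed
            )
            spec = ModelSpec(name="path", features=("f",))
            pipe, _ = _make_classifier(spec, cfg.seed)
            pipe.set_params(clf__C=1.0 / cfg.strength, clf__l1_ratio=cfg.l1_ratio)
            aucs = []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for tr, te in cv.split(X, y):
                    pipe.fit(X[tr], y[tr])
                    aucs.append(roc_auc_score(y[te], pipe.predict_proba(X[te])[:, 1]))
            rows.append(
                {
                    "k": k,
                    "members": members,
                    "auc": float(np.mean(aucs)),
                    "fold_sd": float(np.std(aucs, ddof=1)),
                }
            )
        return pd.DataFrame(rows, index=[f"K{r['k']}" for r in rows])


@dataclass
class PanelSelectionResults:
    frequency_panel: FrequencyPanel
    path: PanelPath
    selections: list[list[str]]
    univariate_auc: pd.Series
    config: SelectionConfig = field(repr=False, default=None)

    def summary(self) -> str:
        fp = self.frequency_panel.table
        lines = [
            "Cluster-constrained panel selection "
            f"({self.config.outer_folds} outer folds x {self.config.repeats} repeats "
            f"= {len(self.selections)} run units)",
            "",
            "Selection-frequency panel (after deduplication):",
            fp.to_string() if len(fp) else "  (no feature passed the gain gates)",
            "",
            "K-AUC path:",
            self.path.table[["k", "auc", "fold_sd"]].to_string(
                float_format=lambda v: f"{v:.4f}"
            ),
            "",
            f"1-SE threshold: {self.path.one_se_threshold:.4f}",
            f"Selected panel size (1-SE rule): K = {self.path.selected_k} "
            f"{list(self.path.selected_members)}",
        ]
        return "\n".join(lines)
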