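"""Classifier evaluation under nested cross-validation.

The primary classifier is elastic-net-penalized logistic regression; linear
and RBF support-vector machines, random forest and gradient boosting are
optional comparators behind the same interface.  Features are
median-imputed and standardized inside the training pipeline (so no test
information leaks into the preprocessing), hyperparameters are tuned on the
inner folds by AUC, and every sample's out-of-fold (OOF) probability comes
from a model never trained on it.  Pooled OOF probabilities feed ROC/PR
metrics, the Brier score, bootstrap confidence intervals, equal-width-bin
calibration (ECE), decision-curve analysis and clinically prespecified
operating points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import io
from .covariates import ConfusionCounts, OperatingPoint, confusion_metrics, youden_select

__all__ = [
    "ModelSpec",
    "EvalReport",
    "DecisionCurve",
    "fit_penalized_logistic",
    "NestedCVEvaluator",
    "nested_oof_eval",
    "calibration_metrics",
    "decision_curve",
    "operating_points",
]

# inner-CV tuning grid for the elastic-net logistic model
DEFAULT_LOGISTIC_GRID = {
    "clf__C": [1.0 / s for s in (0.001, 0.01, 0.1, 1.0, 10.0)],
    "clf__l1_ratio": [0.1, 0.5, 0.9],
}
DEFAULT_PT_GRID = np.round(np.arange(0.01, 0.501, 0.01), 4)


@dataclass(frozen=True)
class ModelSpec:
    """One named classifier configuration.

    ``features`` are miRNA IDs; ``baseline`` the clinical covariates
    ("age" and/or "sex"); at least one predictor must be present.
    """

    name: str
    features: tuple[str, ...] = ()
    baseline: tuple[str, ...] = ()
    classifier: str = "penalized_logistic"
    class_weighting: bool = True
    grid: dict | None = None

    def __post_init__(self) -> None:
        if not self.features and not self.baseline:
            raise ValueError("model spec has no predictors")
        bad = set(self.baseline) - {"age", "sex"}
        if bad:
            raise ValueError(f"unsupported baseline covariates: {sorted(bad)}")


def _make_classifier(spec: ModelSpec, seed: int):
    cw = "balanced" if spec.class_weighting else None
    if spec.classifier == "penalized_logistic":
        clf = LogisticRegression(
            penalty="elasticnet",
            solver="saga",
            l1_ratio=0.5,
            C=10.0,
            max_iter=5000,
            class_weight=cw,
            random_state=seed,
        )
        grid = spec.grid if spec.grid is not None else DEFAULT_LOGISTIC_GRID
    elif spec.classifier == "linear_svm":
        clf = SVC(kernel="linear", probability=True, class_weight=cw, random_state=seed)
        grid = spec.grid if spec.grid is not None else {"clf__C": [0.1, 1.0, 10.0]}
    elif spec.classifier == "rbf_svm":
        clf = SVC(kernel="rbf", probability=True, class_weight=cw, random_state=seed)
        grid = spec.grid if spec.grid is not None else {"clf__C": [0.1, 1.0, 10.0]}
    elif spec.classifier == "random_forest":
        clf = RandomForestClassifier(
            n_estimators=300, class_weight=cw, random_state=seed, n_jobs=1
        )
        grid = spec.grid if spec.grid is not None else {"clf__max_depth": [3, 6, None]}
    elif spec.classifier == "gradient_boosting":
        clf = GradientBoostingClassifier(random_state=seed)
        grid = spec.grid if spec.grid is not None else {"clf__max_depth": [2, 3]}
    else:
        raise ValueError(f"unknown classifier {spec.classifier!r}")
    pipe = Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("clf", clf),
        ]
    )
    return pipe, grid


def fit_penalized_logistic(
    X,
    y,
    l1_ratio: float = 0.5,
    strength: float = 1.0,
    weights=None,
    class_weighting: bool = False,
    seed: int = 0,
):
    """Fit elastic-net logistic regression inside the imputation/scaling pipeline.

    The penalty is ``strength * [l1_ratio*L1 + (1-l1_ratio)/2*L2]`` on the
    standardized features.  Returns the fitted pipeline; coefficients and
    intercept are exposed as attributes and probabilities via
    ``predict_proba``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("y must contain both classes")
    if strength <= 0:
        raise ValueError("penalty strength must be positive")
    pipe = Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            (
                "clf",
                LogisticRegression(
                    penalty="elasticnet",
                    solver="saga",
                    l1_ratio=l1_ratio,
                    C=1.0 / strength,
                    max_iter=20000,
                    class_weight="balanced" if class_weighting else None,
                    random_state=seed,
                ),
            ),
        ]
    )
    fit_params = {}
    if weights is not None:
        fit_params["clf__sample_weight"] = np.asarray(weights, float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pipe.fit(X, y, **fit_params)
    if not np.all(np.isfinite(pipe["scale"].transform(pipe["impute"].transform(X)))):
        raise ValueError("non-finite values remain after imputation")
    pipe.coef_ = pipe["clf"].coef_.ravel()
    pipe.intercept_ = float(pipe["clf"].intercept_[0])
    return pipe


@dataclass
class DecisionCurve:
    """Net benefit across threshold probabilities, with reference strategies."""

    pt: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray
    prevalence: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pt": self.pt,
                "net_benefit": self.net_benefit,
                "treat_all": self.treat_all,
                "treat_none": self.treat_none,
            }
        ).set_index("pt")


@dataclass
class EvalReport:
    """Out-of-fold evaluation of one model spec."""

    spec: ModelSpec
    oof_probs: pd.Series
    y: pd.Series
    auc: float
    auc_ci: tuple[float, float]
    ap: float
    brier: float
    ece: float
    calibration_bins: pd.DataFrame
    dca: DecisionCurve
    operating_points: pd.DataFrame
    fold_aucs: np.ndarray
    best_params: list = field(default_factory=list)

    def summary(self) -> str:
        lo, hi = self.auc_ci
        lines = [
            f"Model {self.spec.name!r} ({self.spec.classifier}) — "
            f"{len(self.oof_probs)} samples, prevalence {self.y.mean():.3f}",
            f"  OOF AUC:   {self.auc:.4f} (95% CI {lo:.4f}-{hi:.4f})",
            f"  OOF AP:    {self.ap:.4f}",
            f"  Brier:     {self.brier:.4f}",
            f"  ECE:       {self.ece:.4f}",
            "",
            "Operating points (rule: prob >= threshold => AD):",
            self.operating_points.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


def _model_frame(
    expr: pd.DataFrame | None, pheno: pd.DataFrame, spec: ModelSpec
) -> pd.DataFrame:
    parts = []
    if spec.features:
        missing = set(spec.features) - set(expr.index)
        if missing:
            raise KeyError(f"features absent from matrix: {sorted(missing)[:5]}")
        parts.append(expr.loc[list(spec.features)].T)
    if "age" in spec.baseline:
        parts.append(pheno["age"].astype(float).rename("age"))
    if "sex" in spec.baseline:
        parts.append((pheno["sex"] == "female").astype(float).rename("sex_female"))
    X = pd.concat(parts, axis=1)
    return X


class NestedCVEvaluator:
    """Nested stratified cross-validation for one model spec.

    Outer folds provide generalization estimates; inner folds tune
    hyperparameters by AUC.  With ``repeats`` > 1 the OOF probabilities are
    averaged across repeats before pooled metrics are computed.
    Single-threaded and deterministic given ``seed``.
    """

    def __init__(
        self,
        expr: pd.DataFrame | None,
        pheno: pd.DataFrame,
        spec: ModelSpec,
        outer: int = 5,
        inner: int = 5,
        repeats: int = 1,
        seed: int = 0,
        sample_weights: np.ndarray | None = None,
        n_bootstrap: int = 2000,
    ) -> None:
        io.validate_phenotype(pheno)
        if expr is not None:
            io.check_aligned(expr, pheno)
            pheno = pheno.loc[expr.columns]
        self.X = _model_frame(expr, pheno, spec)
        self.y = (pheno["diagnosis"] == "AD").astype(int)
        if min(np.bincount(self.y)) < outer:
            raise ValueError("each class must have at least `outer` members")
        self.spec = spec
        self.outer = outer
        self.inner = inner
        self.repeats = repeats
        self.seed = seed
        self.sample_weights = sample_weights
        self.n_bootstrap = n_bootstrap

    def fit(self) -> EvalReport:
        X = self.X.to_numpy(float)
        y = self.y.to_numpy()
        prob_sum = np.zeros(len(y))
        fold_aucs = []
        best_params: list = []
        for rep in range(self.repeats):
            outer_cv = StratifiedKFold(
                n_splits=self.outer, shuffle=True, random_state=self.seed + 1000 * rep
            )
            for tr, te in outer_cv.split(X, y):
                w_tr = (
                    None
                    if self.sample_weights is None
                    else np.asarray(self.sample_weights, float)[tr]
                )
                model = self._fit_inner(X[tr], y[tr], best_params, w_tr)
                p = model.predict_proba(X[te])[:, 1]
                prob_sum[te] += p
                fold_aucs.append(roc_auc_score(y[te], p))
        oof = prob_sum / self.repeats
        return self._report(oof, np.asarray(fold_aucs), best_params)

    def _fit_inner(self, X_tr, y_tr, best_params: list, w_tr=None):
        pipe, grid = _make_classifier(self.spec, self.seed)
        fit_params = {} if w_tr is None else {"clf__sample_weight": w_tr}
        # hyperparameter search does not route per-sample weights; with an
        # explicit weight vector the default parameters are used directly
        n_grid = int(np.prod([len(v) for v in grid.values()])) if grid else 1
        if w_tr is not None:
            n_grid = 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if n_grid > 1:
                inner_cv = StratifiedKFold(
                    n_splits=self.inner, shuffle=True, random_state=self.seed + 7
                )
                search = GridSearchCV(
                    pipe, grid, scoring="roc_auc", cv=inner_cv, n_jobs=1, refit=True
                )
                search.fit(X_tr, y_tr, **fit_params)
                best_params.append(search.best_params_)
                return search.best_estimator_
            model = clone(pipe)
            if grid:
                model.set_params(**{k: v[0] for k, v in grid.items()})
            model.fit(X_tr, y_tr, **fit_params)
            return model

    def _report(self, oof: np.ndarray, fold_aucs: np.ndarray, best_params) -> EvalReport:
        y = self.y.to_numpy()
        auc = float(roc_auc_score(y, oof))
        ap = float(average_precision_score(y, oof))
        brier = float(np.mean((oof - y) ** 2))
        ci = _stratified_bootstrap_auc_ci(
            oof, y, n_boot=self.n_bootstrap, seed=self.seed
        )
        ece, bins = calibration_metrics(oof, y)
        dca = decision_curve(oof, y)
        ops = operating_points(oof, y)
        return EvalReport(
            spec=self.spec,
            oof_probs=pd.Series(oof, index=self.y.index, name="oof_prob"),
            y=self.y,
            auc=auc,
            auc_ci=ci,
            ap=ap,
            brier=brier,
            ece=ece,
            calibration_bins=bins,
            dca=dca,
            operating_points=ops,
            fold_aucs=fold_aucs,
            best_params=best_params,
        )


def nested_oof_eval(
    expr: pd.DataFrame | None,
    pheno: pd.DataFrame,
    spec: ModelSpec,
    outer: int = 5,
    inner: int = 5,
    repeats: int = 1,
    seed: int = 0,
    n_bootstrap: int = 2000,
) -> EvalReport:
    """Functional wrapper over :class:`NestedCVEvaluator`."""
    return NestedCVEvaluator(
        expr, pheno, spec, outer, inner, repeats, seed, n_bootstrap=n_bootstrap
    ).fit()


def _stratified_bootstrap_auc_ci(
    probs: np.ndarray, y: np.ndarray, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Percentile 95% CI for the OOF AUC by class-stratified bootstrap."""
    rng = np.random.default_rng(seed)
    pos = np.where(y == 1)[0]
    neg = np.where(y == 0)[0]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.r_[rng.choice(pos, pos.size), rng.choice(neg, neg.size)]
        aucs[b] = roc_auc_score(y[idx], probs[idx])
    return float(np.quantile(aucs, 0.025)), float(np.quantile(aucs, 0.975))


def calibration_metrics(
    oof_probs, y, n_bins: int = 10
) -> tuple[float, pd.DataFrame]:
    """Expected calibration error over equal-width probability bins.

    ECE = sum over non-empty bins of (bin count / n) * |mean prob - observed
    rate|.  The bin table reports counts, mean predicted probability and
    observed event rate per bin.
    """
    p = np.asarray(oof_probs, float)
    y = np.asarray(y).astype(int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(p, edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    ece = 0.0
    for b in range(n_bins):
        mask = which == b
        count = int(mask.sum())
        if count == 0:
            continue
        mean_p = float(p[mask].mean())
        rate = float(y[mask].mean())
        ece += count / p.size * abs(mean_p - rate)
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "count": count,
                "mean_prob": mean_p,
                "observed_rate": rate,
            }
        )
    return float(ece), pd.DataFrame(rows)


def decision_curve(oof_probs, y, pt_grid=DEFAULT_PT_GRID) -> DecisionCurve:
    """Decision-curve analysis on OOF probabilities.

    At each threshold probability pt, samples with prob >= pt are treated;
    NB(pt) = TP/N - (FP/N) * pt/(1-pt).  Treat-all has NB = prevalence -
    (1-prevalence)*pt/(1-pt); treat-none is 0 everywhere.
    """
    p = np.asarray(oof_probs, float)
    y = np.asarray(y).astype(int)
    pt = np.asarray(pt_grid, float)
    if np.any(pt >= 1.0) or np.any(pt <= 0.0):
        raise ValueError("pt grid must lie strictly inside (0, 1)")
    n = y.size
    prevalence = float(y.mean())
    odds = pt / (1.0 - pt)
    treated = p[None, :] >= pt[:, None]
    tp = (treated & (y == 1)[None, :]).sum(axis=1)
    fp = (treated & (y == 0)[None, :]).sum(axis=1)
    nb = tp / n - fp / n * odds
    treat_all = prevalence - (1.0 - prevalence) * odds
    return DecisionCurve(
        pt=pt,
        net_benefit=nb,
        treat_all=treat_all,
        treat_none=np.zeros_like(pt),
        prevalence=prevalence,
    )


def operating_points(oof_probs, y) -> pd.DataFrame:
    """Three prespecified operating points on the OOF probabilities.

    Rows: Youden-optimal; the highest-sensitivity threshold with
    specificity >= 0.90; the highest-specificity threshold with
    sensitivity >= 0.90.  Rule: prob >= threshold => AD.  An unattainable
    constraint yields a row of missing metrics with a warning.
    """
    p = np.asarray(oof_probs, float)
    y = np.asarray(y).astype(int)
    youden = youden_select(p, y)
    rows = {"youden": youden}
    rows["spec_ge_0.90"] = _constrained_point(p, y, "specificity", 0.90, "sensitivity")
    rows["sens_ge_0.90"] = _constrained_point(p, y, "sensitivity", 0.90, "specificity")
    table = pd.DataFrame(
        {
            name: {
                "threshold": op.threshold,
                "sensitivity": op.sensitivity,
                "specificity": op.specificity,
                "ppv": op.ppv,
                "npv": op.npv,
            }
            for name, op in rows.items()
        }
    ).T
    table.index.name = "constraint"
    return table


def _constrained_point(
    p: np.ndarray, y: np.ndarray, constraint: str, floor: float, maximize: str
) -> OperatingPoint:
    best = None
    for thr in np.r_[-np.inf, np.unique(p), np.inf]:
        pred = p >= thr
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        tn = int(np.sum(~pred & (y == 0)))
        fn = int(np.sum(~pred & (y == 1)))
        op = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
        op.threshold = float(thr)
        c_val = getattr(op, constraint)
        m_val = getattr(op, maximize)
        if c_val is None or m_val is None or c_val < floor:
            continue
        if best is None or m_val > getattr(best, maximize) + 1e-12:
            best = op
    if best is None:
        warnings.warn(
            f"operating-point constraint {constraint} >= {floor} unattainable",
            stacklevel=2,
        )
        return OperatingPoint(None, None, None, None, None, None, None)
    return best
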