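"""End-to-end pipeline orchestration with a single config and output manifest.

Stages run in order: synthesize -> preprocess (normalize + variance filter)
-> de -> direction (directionality tests + signature score) -> covariates
-> network -> select -> evaluate.  Any stage can be skipped by name.  All
randomness derives from one top-level seed via per-stage hashed seeds, so
reruns of the same config are file-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import covariates as cov_mod
from . import de as de_mod
from . import io
from . import network as net_mod
from . import panel as panel_mod
from . import signature as sig_mod
from .models import ModelSpec, nested_oof_eval

logger = logging.getLogger("seromir")

STAGES = (
    "synthesize",
    "preprocess",
    "de",
    "direction",
    "covariates",
    "network",
    "select",
    "evaluate",
)


@dataclass
class RunManifest:
    config_digest: str
    seed: int
    version: str
    stages: list[dict] = field(default_factory=list)

    def to_json(self, path: str) -> str:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
        return path


def stage_seed(top_seed: int, stage: str) -> int:
    """Derive a per-stage seed by hashing (top seed, stage name)."""
    digest = hashlib.sha256(f"{top_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def config_digest(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def load_config(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "skip": [],
    "cohort": {},  # overrides for the study-like synthetic cohort
    "input": None,  # {"expression": path, "phenotype": path} to skip synthesis
    "de": {
        "already_log2": True,
        "sd_quantile": 0.25,
        "covariates": ["age", "sex", "apoe4"],
        "apoe_coding": "continuous",
        "trend": True,
        "alpha": 0.05,
    },
    "network": {"thresholds": [0.90, 0.85, 0.80, 0.75, 0.70], "primary": 0.80,
                "min_pairs": 10},
    "select": {},
    "evaluate": {"outer": 5, "inner": 5, "repeats": 1, "grid": None,
                 "baseline": ["age", "sex"]},
}


def _merged(config: dict | None) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def run_pipeline(config: dict | str | None, outdir: str) -> RunManifest:
    """Execute the full workflow; returns (and writes) the run manifest.

    ``config`` is a dict or a YAML path; missing keys fall back to the
    study-like defaults.  A stage failure aborts with the stage name after
    writing the partial manifest.
    """
    if isinstance(config, str):
        config = load_config(config)
    cfg = _merged(config)
    os.makedirs(outdir, exist_ok=True)
    seed = int(cfg["seed"])
    skip = set(cfg.get("skip") or [])
    unknown = skip - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) in skip list: {sorted(unknown)}")
    manifest = RunManifest(
        config_digest=config_digest(cfg),
        seed=seed,
        version=__import__("seromir").__version__,
    )
    state: dict = {}

    def record(stage: str, status: str, outputs: dict[str, str], n_rows: int | None,
               t0: float) -> None:
        manifest.stages.append(
            {
                "stage": stage,
                "status": status,
                "outputs": outputs,
                "n_rows": n_rows,
                "elapsed_s": round(time.time() - t0, 3),
            }
        )

    for stage in STAGES:
        t0 = time.time()
        if stage in skip:
            logger.info("stage %s: skipped", stage)
            record(stage, "skipped", {}, None, t0)
            continue
        logger.info("stage %s: start", stage)
        try:
            outputs, n_rows = _STAGE_FUNCS[stage](cfg, seed, outdir, state)
        except Exception:
            manifest.to_json(os.path.join(outdir, "manifest.json"))
            logger.exception("stage %s failed", stage)
            raise RuntimeError(f"pipeline stage {stage!r} failed") from None
        record(stage, "completed", outputs, n_rows, t0)
        logger.info("stage %s: done in %.1fs", stage, time.time() - t0)

    manifest.to_json(os.path.join(outdir, "manifest.json"))
    return manifest


def _stage_synthesize(cfg, seed, outdir, state):
    if cfg.get("input"):
        expr = io.read_expression(cfg["input"]["expression"])
        pheno = io.read_phenotype(cfg["input"]["phenotype"])
        paths = {}
    else:
        overrides = dict(cfg.get("cohort") or {})
        overrides.setdefault("seed", stage_seed(seed, "synthesize"))
        for key in ("candidate_positive", "candidate_negative"):
            if key in overrides:
                overrides[key] = tuple(overrides[key])
        ccfg = cohort_mod.gse120584_like_config(**overrides)
        expr, pheno = cohort_mod.generate_cohort(ccfg)
        paths = cohort_mod.write_dataset(expr, pheno, outdir)
    state["expr_raw"], state["pheno"] = expr, pheno
    state["positive"] = list(
        (cfg.get("cohort") or {}).get("candidate_positive", cohort_mod.POSITIVE_CANDIDATES)
    )
    state["negative"] = list(
        (cfg.get("cohort") or {}).get("candidate_negative", cohort_mod.NEGATIVE_CANDIDATES)
    )
    return paths, expr.shape[0]


def _stage_preprocess(cfg, seed, outdir, state):
    d = cfg["de"]
    norm = de_mod.normalize_log2_quantile(
        state["expr_raw"], already_log2=d["already_log2"]
    )
    filtered = de_mod.filter_by_rowsd(norm, quantile=d["sd_quantile"])
    state["expr"] = filtered
    path = io.write_expression(filtered, os.path.join(outdir, "normalized.tsv"))
    return {"normalized": path}, filtered.shape[0]


def _stage_de(cfg, seed, outdir, state):
    d = cfg["de"]
    res = de_mod.ModeratedDE(
        state["expr"],
        state["pheno"],
        covariates=tuple(d["covariates"]),
        apoe_coding=d["apoe_coding"],
        trend=d["trend"],
    ).fit()
    state["de"] = res
    path = res.to_tsv(os.path.join(outdir, "de_results.tsv"))
    return {"de_results": path}, len(res.table)


def _stage_direction(cfg, seed, outdir, state):
    alpha = cfg["de"]["alpha"]
    pos = sig_mod.CandidateSet(tuple(state["positive"]), "positive")
    neg = sig_mod.CandidateSet(tuple(state["negative"]), "negative")
    rows = []
    for cset in (pos, neg):
        rep = sig_mod.direction_report(state["de"], cset, alpha=alpha)
        rows.append(
            {
                "set": cset.direction,
                "n_members": len(cset.members),
                "n_present": len(rep.consistency),
                "n_consistent": rep.n_consistent,
                "mean_rank_p": rep.mean_rank_p,
                "sign_test_p": rep.sign_test_p,
                "signed_rank_p": rep.signed_rank_p,
            }
        )
    report = pd.DataFrame(rows).set_index("set")
    score = sig_mod.compute_signature_score(state["expr"], pos, neg)
    assoc = sig_mod.test_signature_association(score, state["pheno"])
    report_path = os.path.join(outdir, "direction_report.tsv")
    report.to_csv(report_path, sep="\t")
    score_path = os.path.join(outdir, "signature_scores.tsv")
    out = score.to_frame()
    out.to_csv(score_path, sep="\t")
    with open(os.path.join(outdir, "signature_association.json"), "w") as fh:
        json.dump(assoc, fh, indent=2)
    state["signature_score"] = score
    return {"direction_report": report_path, "signature_scores": score_path}, len(report)


def _stage_covariates(cfg, seed, outdir, state):
    pheno = state["pheno"]
    y = (pheno["diagnosis"] == "AD").astype(int)
    rows = []
    for name in ("age", "sex", "apoe4"):
        scores = cov_mod._covariate_vector(pheno, name)
        auc, ap = cov_mod.rank_metrics(scores, y)
        op = cov_mod.youden_select(scores, y)
        _, summary = cov_mod.crossval_univariate(
            scores, y, seed=stage_seed(seed, "covariates")
        )
        rows.append(
            {
                "covariate": name,
                "auc": auc,
                "ap": ap,
                "youden_j": op.youden_j,
                "threshold": op.threshold,
                "sensitivity": op.sensitivity,
                "specificity": op.specificity,
                "cv_auc_mean": summary.loc["auc", "mean"],
                "cv_auc_sd": summary.loc["auc", "sd"],
            }
        )
    table = pd.DataFrame(rows).set_index("covariate")
    path = os.path.join(outdir, "covariate_metrics.tsv")
    table.to_csv(path, sep="\t")

    cand = [f for f in state["positive"] + state["negative"] if f in state["expr"].index]
    assoc = pd.concat(
        [
            cov_mod.partial_rank_assoc(
                state["expr"].loc[cand], pheno, target,
                tuple(a for a in ("age", "sex", "apoe4") if a != target),
            )
            for target in ("age", "sex", "apoe4")
        ]
    )
    assoc_path = os.path.join(outdir, "mirna_covariate_assoc.tsv")
    assoc.to_csv(assoc_path, sep="\t")
    return {"covariate_metrics": path, "associations": assoc_path}, len(table)


def _stage_network(cfg, seed, outdir, state):
    n = cfg["network"]
    cand = [f for f in state["positive"] + state["negative"] if f in state["expr"].index]
    corr = net_mod.spearman_matrix(state["expr"].loc[cand], min_pairs=n["min_pairs"])
    scan = net_mod.scan_thresholds(corr, sorted(n["thresholds"], reverse=True))
    clusters = net_mod.cluster_components(corr, n["primary"])
    state["clusters"] = clusters
    rho_path = os.path.join(outdir, "spearman_rho.tsv")
    corr.rho.to_csv(rho_path, sep="\t")
    scan_path = os.path.join(outdir, "threshold_scan.tsv")
    scan.to_csv(scan_path, sep="\t")
    cl_path = os.path.join(outdir, "clusters.tsv")
    clusters.assignments.to_csv(cl_path, sep="\t")
    sizes = clusters.assignments.value_counts()
    if sizes.max() >= 2:
        me = net_mod.module_eigengene(
            state["expr"], clusters.members(sizes.idxmax())
        )
        me.values.to_csv(os.path.join(outdir, "module_eigengene.tsv"), sep="\t")
    return {"rho": rho_path, "scan": scan_path, "clusters": cl_path}, len(cand)


def _stage_select(cfg, seed, outdir, state):
    overrides = dict(cfg.get("select") or {})
    overrides.setdefault("seed", stage_seed(seed, "select"))
    if "baseline" in overrides:
        overrides["baseline"] = tuple(overrides["baseline"])
    scfg = panel_mod.SelectionConfig(**overrides)
    cand = [f for f in state["positive"] + state["negative"] if f in state["expr"].index]
    selector = panel_mod.PanelSelector(
        state["expr"].loc[cand], state["pheno"], state["clusters"], scfg
    )
    res = selector.fit()
    state["panel"] = res
    freq_path = os.path.join(outdir, "frequency_panel.tsv")
    res.frequency_panel.table.to_csv(freq_path, sep="\t")
    path_path = os.path.join(outdir, "k_auc_path.tsv")
    res.path.table.assign(
        members=[";".join(m) for m in res.path.table["members"]]
    ).to_csv(path_path, sep="\t")
    return {"frequency_panel": freq_path, "k_auc_path": path_path}, len(
        res.frequency_panel.table
    )


def _stage_evaluate(cfg, seed, outdir, state):
    e = cfg["evaluate"]
    baseline = tuple(e.get("baseline") or ())
    panel_members = tuple(state["panel"].path.selected_members) if "panel" in state else ()
    specs = [ModelSpec(name="baseline", baseline=baseline, grid=e["grid"])]
    if panel_members:
        specs.append(
            ModelSpec(
                name=f"K{len(panel_members)}+{'+'.join(baseline)}",
                features=panel_members,
                baseline=baseline,
                grid=e["grid"],
            )
        )
    outputs = {}
    rows = []
    for spec in specs:
        report = nested_oof_eval(
            state["expr"] if spec.features else None,
            state["pheno"],
            spec,
            outer=e["outer"],
            inner=e["inner"],
            repeats=e["repeats"],
            seed=stage_seed(seed, "evaluate"),
            n_bootstrap=e.get("n_bootstrap", 2000),
        )
        tag = spec.name.replace("+", "_")
        dca_path = os.path.join(outdir, f"dca_{tag}.tsv")
        report.dca.to_frame().to_csv(dca_path, sep="\t")
        ops_path = os.path.join(outdir, f"operating_points_{tag}.tsv")
        report.operating_points.to_csv(ops_path, sep="\t")
        outputs[f"dca_{tag}"] = dca_path
        outputs[f"operating_points_{tag}"] = ops_path
        rows.append(
            {
                "model": spec.name,
                "auc": report.auc,
                "auc_ci_low": report.auc_ci[0],
                "auc_ci_high": report.auc_ci[1],
                "ap": report.ap,
                "brier": report.brier,
                "ece": report.ece,
            }
        )
    summary = pd.DataFrame(rows).set_index("model")
    sum_path = os.path.join(outdir, "model_summary.tsv")
    summary.to_csv(sum_path, sep="\t")
    outputs["model_summary"] = sum_path
    return outputs, len(summary)


_STAGE_FUNCS = {
    "synthesize": _stage_synthesize,
    "preprocess": _stage_preprocess,
    "de": _stage_de,
    "direction": _stage_direction,
    "covariates": _stage_covariates,
    "network": _stage_network,
    "select": _stage_select,
    "evaluate": _stage_evaluate,
}
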