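"""Plotting helpers for the panel-selection and evaluation results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .models import EvalReport
from .panel import PanelPath

__all__ = [
    "plot_k_auc_path",
    "plot_decision_curve",
    "plot_calibration",
    "plot_threshold_scan",
]


def plot_k_auc_path(path: PanelPath, ax=None):
    """Cross-validated AUC as a function of panel size K with the 1-SE line."""
    ax = ax or plt.gca()
    t = path.table
    ax.errorbar(t["k"], t["auc"], yerr=t.get("fold_sd"), marker="o", capsize=3)
    ax.axhline(path.one_se_threshold, ls="--", color="grey", label="1-SE threshold")
    ax.axvline(path.selected_k, ls=":", color="red", label=f"selected K={path.selected_k}")
    ax.set_xlabel("panel size K")
    ax.set_ylabel("cross-validated AUC")
    ax.legend()
    return ax


def plot_decision_curve(report: EvalReport, ax=None):
    """Net benefit vs threshold probability with treat-all/none references."""
    ax = ax or plt.gca()
    d = report.dca
    ax.plot(d.pt, d.net_benefit, label=report.spec.name)
    ax.plot(d.pt, d.treat_all, ls="--", color="grey", label="treat all")
    ax.plot(d.pt, d.treat_none, ls=":", color="black", label="treat none")
    ax.set_xlabel("threshold probability $p_t$")
    ax.set_ylabel("net benefit")
    ax.set_ylim(bottom=max(-0.05, ax.get_ylim()[0]))
    ax.legend()
    return ax


def plot_calibration(report: EvalReport, ax=None):
    """Reliability diagram from the equal-width calibration bins."""
    ax = ax or plt.gca()
    b = report.calibration_bins
    ax.plot([0, 1], [0, 1], ls="--", color="grey")
    ax.plot(b["mean_prob"], b["observed_rate"], marker="o")
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("observed AD rate")
    ax.set_title(f"{report.spec.name}: ECE = {report.ece:.3f}")
    return ax


def plot_threshold_scan(scan: pd.DataFrame, ax=None):
    """Cluster count / max size / singleton count across |rho| thresholds."""
    ax = ax or plt.gca()
    for col in ("n_clusters", "max_cluster_size", "n_singletons"):
        ax.plot(scan.index, scan[col], marker="o", label=col)
    ax.invert_xaxis()
    ax.set_xlabel(r"$|\rho|$ threshold")
    ax.set_ylabel("count")
    ax.legend()
    return ax
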