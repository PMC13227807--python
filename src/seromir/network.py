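"""Correlation-structure analysis of candidate miRNAs.

Pairwise Spearman correlation with pairwise-complete observations, a
|rho|-thresholded undirected network whose connected components define
miRNA clusters, a threshold sensitivity scan, and the module eigengene
(first principal component of the z-scored cluster) summarizing a cluster's
expression per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "CorrelationMatrix",
    "ClusterMap",
    "ModuleEigengene",
    "spearman_matrix",
    "cluster_components",
    "scan_thresholds",
    "module_eigengene",
]


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman rho matrix with pairwise-complete sample counts."""

    rho: pd.DataFrame
    n_obs: pd.DataFrame

    @property
    def feature_ids(self) -> list[str]:
        return list(self.rho.index)


@dataclass
class ClusterMap:
    """Connected-component clustering of the |rho|-thresholded network."""

    threshold: float
    assignments: pd.Series  # feature_id -> cluster ID

    def members(self, cluster_id: str) -> list[str]:
        return list(self.assignments.index[self.assignments == cluster_id])

    def cluster_of(self, feature_id: str) -> str | None:
        return self.assignments.get(feature_id)

    @property
    def summary(self) -> dict[str, int]:
        sizes = self.assignments.value_counts()
        multi = sizes[sizes >= 2]
        return {
            "n_clusters": int(len(multi)),
            "max_cluster_size": int(sizes.max()) if len(sizes) else 0,
            "n_singletons": int((sizes == 1).sum()),
        }


@dataclass
class ModuleEigengene:
    cluster_id: str
    values: pd.Series  # per-sample, unit variance
    variance_explained: float
    loadings: pd.Series


def spearman_matrix(expr: pd.DataFrame, min_pairs: int = 10) -> CorrelationMatrix:
    """Feature-feature Spearman correlation over pairwise-complete samples.

    Entries backed by fewer than ``min_pairs`` complete pairs are missing.
    """
    data = expr.T  # samples x features
    rho = data.corr(method="spearman", min_periods=max(min_pairs, 2))
    present = data.notna().to_numpy(float)
    n_obs = pd.DataFrame(
        (present.T @ present).astype(int), index=rho.index, columns=rho.columns
    )
    np.fill_diagonal(rho.to_numpy(), 1.0)
    return CorrelationMatrix(rho=rho, n_obs=n_obs)


def cluster_components(corr: CorrelationMatrix, threshold: float) -> ClusterMap:
    """Clusters = connected components of the graph with edges |rho| >= threshold.

    Missing correlations contribute no edge (conservative connectivity).
    Singletons are retained as size-1 clusters; cluster IDs are the
    lexicographically smallest member, so labels are order-invariant.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    ids = corr.feature_ids
    a = corr.rho.to_numpy(float).copy()
    np.fill_diagonal(a, 0.0)
    adj = np.nan_to_num(np.abs(a), nan=0.0) >= threshold
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    names = {}
    for comp in range(n_comp):
        members = [ids[i] for i in np.where(labels == comp)[0]]
        names[comp] = min(members)
    assignments = pd.Series(
        [names[c] for c in labels], index=pd.Index(ids, name="feature_id"), name="cluster"
    )
    return ClusterMap(threshold=threshold, assignments=assignments)


def scan_thresholds(
    corr: CorrelationMatrix,
    thresholds=(0.90, 0.85, 0.80, 0.75, 0.70),
) -> pd.DataFrame:
    """Cluster-structure summary across a descending |rho| threshold grid.

    As the threshold relaxes, the maximum cluster size is non-decreasing
    and the singleton count non-increasing.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds, reverse=True):
        raise ValueError("thresholds must be sorted in descending order")
    rows = []
    for thr in thresholds:
        cm = cluster_components(corr, thr)
        rows.append({"threshold": thr, **cm.summary})
    return pd.DataFrame(rows).set_index("threshold")


def module_eigengene(expr: pd.DataFrame, members) -> ModuleEigengene:
    """First principal component of a z-scored feature cluster.

    Member rows are median-imputed, z-scored across samples, and the PC1
    score vector is scaled to unit variance with the sign oriented so the
    mean member loading is positive.  ``variance_explained`` is
    lambda_1 / sum(lambda).
    """
    members = list(members)
    block = expr.loc[members].to_numpy(float)
    if block.shape[0] < 2:
        raise ValueError("module eigengene needs at least 2 member features")
    med = np.nanmedian(block, axis=1, keepdims=True)
    block = np.where(np.isnan(block), med, block)
    sd = block.std(axis=1, ddof=1)
    keep = sd > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 members with nonzero SD")
    members = [m for m, k in zip(members, keep) if k]
    z = (block[keep] - block[keep].mean(axis=1, keepdims=True)) / sd[keep, None]

    # PC1 via SVD of the centered (z-scored) member x sample block
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    if not np.all(s > 0) and s[0] == 0:
        raise ValueError("degenerate covariance in module eigengene")
    scores = vt[0]
    loadings = u[:, 0] * s[0]
    if loadings.mean() < 0:
        scores, loadings = -scores, -loadings
    scores = scores / scores.std(ddof=1)
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    return ModuleEigengene(
        cluster_id=min(members),
        values=pd.Series(scores, index=expr.columns, name="eigengene"),
        variance_explained=var_explained,
        loadings=pd.Series(loadings, index=members, name="loading"),
    )
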