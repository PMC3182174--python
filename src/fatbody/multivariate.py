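"""Sample-structure summaries: correlation-based clustering and PCA.

Group separation is assessed by complete-linkage hierarchical clustering on
``1 - Pearson r`` distances between sample columns of the log2 abundance
table, and by a centered-SVD principal components analysis of the
normalized matrix (centering per protein, no scaling by default).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import InsufficientDataError

__all__ = ["ClusterResult", "PcaResult", "correlation_distances", "hca", "pca", "to_newick"]


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix (merge order, heights)
    samples: list[str]  # leaf set, in input (column) order
    leaf_order: list[str]
    metric: str = "pearson"
    method: str = "complete"

    def cut(self, k: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, k, criterion="maxclust")
        return pd.Series(labels, index=self.samples, name="cluster")


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # proteins x components
    variance_fractions: np.ndarray


def correlation_distances(values: pd.DataFrame, min_overlap: int = 3) -> tuple[np.ndarray, list[str]]:
    """Condensed ``1 - Pearson r`` distances between sample columns.

    Correlations use pairwise-complete observations with a minimum overlap
    of ``min_overlap``; constant columns are excluded with a warning because
    their correlation is undefined.
    """
    usable = []
    for s in values.columns:
        col = values[s].dropna()
        if len(col) >= 2 and col.nunique() > 1:
            usable.append(s)
        else:
            warnings.warn(f"sample {s} is constant or empty; excluded from clustering")
    if len(usable) < 3:
        raise InsufficientDataError("need >= 3 usable samples for clustering")
    sub = values[usable]
    corr = sub.corr(method="pearson", min_periods=min_overlap)
    if corr.isna().any().any():
        bad = corr.columns[corr.isna().any()].tolist()
        raise InsufficientDataError(
            f"insufficient pairwise overlap (< {min_overlap}) for samples {bad}"
        )
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    iu = np.triu_indices_from(dist, k=1)
    return dist[iu], usable


def hca(values: pd.DataFrame, min_overlap: int = 3) -> ClusterResult:
    """Complete-linkage clustering of samples on correlation distance."""
    condensed, samples = correlation_distances(values, min_overlap)
    z = hierarchy.linkage(condensed, method="complete")
    order = hierarchy.leaves_list(z)
    return ClusterResult(
        linkage=z,
        samples=samples,
        leaf_order=[samples[i] for i in order],
    )


def to_newick(result: ClusterResult) -> str:
    """Serialize the sample dendrogram as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(result.linkage)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{result.samples[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def pca(values: pd.DataFrame, scale: bool = False) -> PcaResult:
    """Principal components of samples from a protein x sample table.

    Rows (proteins) with any missing value are dropped; each protein is
    centered (and optionally scaled to unit variance).  Scores come from the
    SVD of the sample x protein matrix; variance fractions sum to 1 over the
    non-degenerate components.
    """
    complete = values.dropna(axis=0, how="any")
    if complete.shape[0] < 2 or complete.shape[1] < 2:
        raise InsufficientDataError("need >= 2 complete proteins and >= 2 samples")
    x = complete.to_numpy(dtype=float).T  # samples x proteins
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else var
    k = len(s)
    comp = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(u * s, index=complete.columns, columns=comp)
    loadings = pd.DataFrame(vt.T, index=complete.index, columns=comp)
    return PcaResult(scores=scores, loadings=loadings, variance_fractions=frac)
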