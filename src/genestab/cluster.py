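"""Correlation-distance hierarchical clustering and the Biological
Homogeneity Index (BHI).

Samples (or genes, for heat-map leaf ordering) are clustered by complete-
linkage agglomeration on the correlation distance ``d = 1 - r``. BHI
measures how homogeneous the clusters are with respect to a biological
category (outcome, ER or PR status):

    BHI(C, B) = (1/K) sum_k [ 1/(n_k (n_k - 1)) ] sum_{i != j in C_k} I(B(i) = B(j)),

an average over ordered within-cluster pairs, bounded by 1 (perfect
homogeneity). Clusters of size < 2 contribute 0 while still counting in K,
penalising fragmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .data import ExpressionMatrix

__all__ = [
    "ClusterAssignment", "BhiResult", "correlation_distance_matrix",
    "hierarchical_cluster", "bhi", "leaf_order",
]


@dataclass
class ClusterAssignment:
    """Sample -> cluster labels (1..K) plus the merge history for audit."""

    labels: pd.Series
    K: int
    linkage_matrix: np.ndarray

    def members(self, k: int) -> list[str]:
        return list(self.labels.index[self.labels == k])


@dataclass(frozen=True)
class BhiResult:
    value: float
    category: str
    K: int


def correlation_distance_matrix(expr: ExpressionMatrix,
                                axis: str = "samples") -> pd.DataFrame:
    """Pairwise ``1 - Pearson r`` distances between samples or genes.

    Symmetric with a zero diagonal, values in [0, 2]. A constant item has no
    defined correlation and raises an error naming it.
    """
    if axis == "samples":
        M = expr.values
        ids = expr.sample_ids
    elif axis == "genes":
        M = expr.values.T
        ids = expr.gene_ids
    else:
        raise ValueError("axis must be 'samples' or 'genes'")
    if M.shape[0] < 2:
        raise ValueError("need at least 2 items to compute distances")
    sd = M.std(axis=1)
    if np.any(sd == 0):
        bad = ids[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"constant vector for {bad!r}; correlation undefined")
    r = np.corrcoef(M)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(0.5 * (d + d.T), 0.0, 2.0)  # enforce symmetry against rounding
    return pd.DataFrame(d, index=ids, columns=ids)


def hierarchical_cluster(distances: pd.DataFrame, K: int,
                         method: str = "complete") -> ClusterAssignment:
    """Agglomerative clustering cut to exactly K clusters.

    Cluster indices are relabelled 1..K in order of first appearance so the
    assignment is deterministic.
    """
    n = distances.shape[0]
    if not 1 <= K <= n:
        raise ValueError(f"K must be in [1, {n}]")
    Z = linkage(squareform(distances.to_numpy(), checks=False), method=method)
    raw = fcluster(Z, t=K, criterion="maxclust")
    if len(np.unique(raw)) != K:
        raise ValueError(
            f"could not cut tree into exactly {K} clusters (got "
            f"{len(np.unique(raw))}); tied merge heights"
        )
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, c in enumerate(raw):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        labels[i] = relabel[c]
    return ClusterAssignment(pd.Series(labels, index=distances.index), K, Z)


def leaf_order(distances: pd.DataFrame, method: str = "complete") -> list[str]:
    """Dendrogram leaf order (for heat-map display of either axis)."""
    Z = linkage(squareform(distances.to_numpy(), checks=False), method=method)
    return [distances.index[i] for i in leaves_list(Z)]


def bhi(assignment: ClusterAssignment, categories: pd.Series,
        category_name: str = "") -> BhiResult:
    """Biological Homogeneity Index of a clustering against category labels.

    ``categories`` maps every clustered sample to its label; the index is
    the K-average of the within-cluster fraction of ordered pairs sharing a
    label.
    """
    categories = pd.Series(categories)
    missing = set(assignment.labels.index) - set(categories.index)
    if missing:
        raise ValueError(f"samples without a category label: {sorted(missing)[:5]}")
    total = 0.0
    for k in range(1, assignment.K + 1):
        members = assignment.members(k)
        nk = len(members)
        if nk < 2:
            continue  # contributes 0, still counts in K
        labs = categories.loc[members].to_numpy()
        matches = sum(int(np.sum(labs == labs[i])) - 1 for i in range(nk))
        total += matches / (nk * (nk - 1))
    return BhiResult(value=total / assignment.K, category=category_name,
                     K=assignment.K)
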