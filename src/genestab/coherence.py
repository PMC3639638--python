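"""Mutual coherence of an expression matrix and the sparsity certificate.

The mutual coherence of a data matrix X (samples x genes) is the largest
absolute normalised inner product between two distinct gene columns,

    mu(X) = max_{i != j} |x_i' x_j| / (||x_i|| ||x_j||),

bounded in [0, 1] and equal to 1 exactly when two columns are collinear.
``mode='raw_cosine'`` uses the columns as-is; ``mode='pearson'`` centres each
column first, making the statistic the absolute Pearson correlation between
genes. A coherence near 1 signals near-duplicate genes: by the sparse-
recovery bound, any solution of X beta = b with fewer than
``(1 + 1/mu) / 2`` non-zeros is necessarily the sparsest possible, so high
coherence certifies at most 1-sparse solutions and explains why many small
gene sets predict interchangeably.

Numerical note: pairwise cosines within 1e-12 of 1 are snapped to exactly
1.0 so collinear columns attain the bound in floating point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ExpressionMatrix

__all__ = [
    "CoherenceReport", "mutual_coherence", "sparsity_bound",
    "sparsity_certificate", "coherence_curve",
]

_SNAP = 1e-12  # collinearity snap tolerance on |cosine|


@dataclass
class CoherenceReport:
    """Mutual coherence with its argmax pair and the sorted pair curve."""

    mu: float
    argmax_pair: tuple[str, str]
    sorted_abs_corr: np.ndarray | None
    n_pairs: int
    mode: str
    top_pairs: list[tuple[str, str, float]] | None = None
    histogram: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def sparsity_bound(self) -> float:
        return sparsity_bound(self.mu)


def mutual_coherence(
    expr: ExpressionMatrix,
    genes=None,
    mode: str = "raw_cosine",
    max_pairs: int = 5_000_000,
    n_bins: int = 10_000,
) -> CoherenceReport:
    """Mutual coherence over a gene subset.

    Stores the full non-increasing |cosine| list when the number of pairs is
    at most ``max_pairs``; beyond that, keeps the exact top-100 pairs plus a
    histogram so memory stays bounded.
    """
    sub = expr.subset_genes(genes) if genes is not None else expr
    X = sub.values
    p = X.shape[1]
    if p < 2:
        raise ValueError("need at least 2 genes")
    if mode == "pearson":
        X = X - X.mean(axis=0)
    elif mode != "raw_cosine":
        raise ValueError("mode must be 'raw_cosine' or 'pearson'")
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        bad = sub.gene_ids[int(np.flatnonzero(norms == 0)[0])]
        what = "constant" if mode == "pearson" else "zero-norm"
        raise ValueError(f"{what} gene column {bad!r}")
    U = X / norms
    C = np.abs(U.T @ U)
    C = np.clip(C, 0.0, 1.0)
    C[C >= 1.0 - _SNAP] = 1.0
    iu = np.triu_indices(p, k=1)
    vals = C[iu]
    amax = int(np.argmax(vals))
    pair = (sub.gene_ids[iu[0][amax]], sub.gene_ids[iu[1][amax]])
    mu = float(vals[amax])
    n_pairs = vals.size
    if n_pairs <= max_pairs:
        order = np.argsort(-vals, kind="stable")
        sorted_vals = vals[order]
        return CoherenceReport(mu, pair, sorted_vals, n_pairs, mode)
    top_idx = np.argpartition(-vals, 100)[:100]
    top_idx = top_idx[np.argsort(-vals[top_idx])]
    top = [(sub.gene_ids[iu[0][t]], sub.gene_ids[iu[1][t]], float(vals[t]))
           for t in top_idx]
    hist, edges = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
    return CoherenceReport(mu, pair, None, n_pairs, mode,
                           top_pairs=top, histogram=(hist, edges))


def sparsity_bound(mu: float) -> float:
    """Sparse-recovery bound ``(1 + 1/mu) / 2`` (infinite when mu = 0)."""
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must be in [0, 1]")
    if mu == 0.0:
        return float("inf")
    return 0.5 * (1.0 + 1.0 / mu)


def sparsity_certificate(mu: float, k: int) -> bool:
    """True iff a k-sparse solution of X beta = b would be certified as the
    sparsest possible, i.e. ``k < (1 + 1/mu) / 2``.

    With mu = 0 (orthogonal columns) the certificate holds vacuously for any
    finite k.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    return k < sparsity_bound(mu)


def coherence_curve(report: CoherenceReport, n_points: int = 200) -> np.ndarray:
    """Sorted |correlation| curve resampled at evenly spaced quantiles.

    Returns an ``(n_points, 2)`` array of (quantile in [0, 1], |corr|),
    non-increasing, with curve(0) = mu and curve(1) = the smallest pair
    correlation — comparable across gene sets with different pair counts.
    """
    if report.sorted_abs_corr is None:
        raise ValueError("report does not retain the full sorted pair list")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    vals = report.sorted_abs_corr
    q = np.linspace(0.0, 1.0, n_points)
    idx = np.round(q * (vals.size - 1)).astype(int)
    return np.column_stack([q, vals[idx]])
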