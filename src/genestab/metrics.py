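"""Classification metrics: empirical AUC, smoothed AUC, error rate.

The empirical AUC is the pair-counting statistic
``(1/(n- n+)) sum_i sum_j H(F(x_j+) - F(x_i-))`` with the Heaviside
convention ``H(0) = 1`` (ties credited as a full success). A conventional
half-tie variant is available via ``ties='half'``; results always state the
convention used. The smoothed AUC replaces ``H`` with a Gaussian CDF
``Phi(z / sigma)``, making the statistic differentiable for boosting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["MetricReport", "empirical_auc", "smoothed_auc", "error_rate"]


@dataclass(frozen=True)
class MetricReport:
    """AUC and error rate of a scorer on one dataset."""

    auc: float
    error_rate: float
    n_pos: int
    n_neg: int
    dataset_tag: str = ""


def empirical_auc(neg_scores, pos_scores, ties: str = "one") -> float:
    """Pair-counting AUC of positive scores against negative scores.

    Parameters
    ----------
    neg_scores, pos_scores : array-like
        Discriminant scores of the y=-1 and y=+1 samples; both non-empty.
    ties : {'one', 'half'}
        Credit for tied pairs: 1 (Heaviside with H(0)=1, the default) or 1/2
        (the Mann-Whitney convention).
    """
    neg = np.asarray(neg_scores, dtype=float)
    pos = np.asarray(pos_scores, dtype=float)
    if neg.size == 0 or pos.size == 0:
        raise ValueError("both score lists must be non-empty")
    if ties not in ("one", "half"):
        raise ValueError("ties must be 'one' or 'half'")
    diff = pos[:, None] - neg[None, :]
    if ties == "one":
        h = (diff >= 0).astype(float)
    else:
        h = (diff > 0) + 0.5 * (diff == 0)
    return float(h.mean())


def smoothed_auc(neg_scores, pos_scores, sigma: float = 1.0) -> float:
    """Gaussian-smoothed AUC: mean of ``Phi((F+ - F-) / sigma)`` over pairs."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    neg = np.asarray(neg_scores, dtype=float)
    pos = np.asarray(pos_scores, dtype=float)
    if neg.size == 0 or pos.size == 0:
        raise ValueError("both score lists must be non-empty")
    return float(norm.cdf((pos[:, None] - neg[None, :]) / sigma).mean())


def error_rate(scores, labels, threshold: float) -> float:
    """Fraction of samples misclassified by ``score >= threshold -> +1``."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = np.where(s >= threshold, 1, -1)
    return float(np.mean(pred != y))
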