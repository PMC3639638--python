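"""The two linear discriminant methods.

``VantVeerClassifier`` is the one-class correlation scorer: a new sample is
scored by *minus* its Pearson correlation — taken across genes — with the
mean expression profile of the good-prognosis (y = -1) training samples, so
large scores mean far from the good-prognosis template and are classified as
metastasis.

``DiagonalLDA`` is Gaussian linear discriminant analysis with the covariance
restricted to its diagonal, the standard choice when genes far outnumber
samples and the full covariance is singular. The score is the estimated
log-likelihood ratio

    F(x) = (mu+ - mu-)' S^-1 x - (1/2) mu+' S^-1 mu+ + (1/2) mu-' S^-1 mu-
           + log(n+/n-),

with S the diagonal of the total-sample (both classes pooled) variance by
default; a pooled within-class variant is available.
"""

from __future__ import annotations

import logging

import numpy as np

from .base import DiscriminantModel, DiscriminantResults, select_threshold

logger = logging.getLogger(__name__)

__all__ = ["VantVeerClassifier", "VantVeerResults", "DiagonalLDA",
           "DldaResults", "dlda_affine_parameters"]


class FitError(ValueError):
    """Raised when a discriminant method cannot be fitted on the data given."""


def _neg_gene_correlation(X: np.ndarray, profile: np.ndarray) -> np.ndarray:
    """Minus the Pearson correlation across genes of each row with profile."""
    pc = profile - profile.mean()
    pnorm = np.linalg.norm(pc)
    if pnorm == 0:
        raise FitError("good-prognosis profile is constant across genes")
    Xc = X - X.mean(axis=1, keepdims=True)
    xnorm = np.linalg.norm(Xc, axis=1)
    if np.any(xnorm == 0):
        raise ValueError("sample expression constant across genes; correlation undefined")
    return -(Xc @ pc) / (xnorm * pnorm)


class VantVeerResults(DiscriminantResults):
    """Results of the one-class correlation method."""

    def __init__(self, model, threshold, train_scores, good_profile):
        self.good_profile = np.asarray(good_profile, dtype=float)
        super().__init__(model, threshold, train_scores)

    def _score_array(self, X: np.ndarray) -> np.ndarray:
        return _neg_gene_correlation(X, self.good_profile)


class VantVeerClassifier(DiscriminantModel):
    """One-class correlation classifier built on the good-prognosis mean."""

    method = "vantveer"

    def __init__(self, expr, phen, genes=None):
        super().__init__(expr, phen, genes)
        if self.p < 2:
            raise FitError("need at least 2 genes for a gene-wise correlation")

    def fit(self) -> VantVeerResults:
        neg = self.X[self.y == -1]
        if neg.shape[0] == 0:
            raise FitError("no good-prognosis (y=-1) training samples")
        profile = neg.mean(axis=0)
        scores = _neg_gene_correlation(self.X, profile)
        threshold = select_threshold(scores, self.y)
        return VantVeerResults(self, threshold, scores, profile)


def dlda_affine_parameters(mean_neg, mean_pos, diag_var, log_prior):
    """Coefficients and intercept of the diagonal-LDA log-likelihood ratio."""
    mean_neg = np.asarray(mean_neg, dtype=float)
    mean_pos = np.asarray(mean_pos, dtype=float)
    diag_var = np.asarray(diag_var, dtype=float)
    coef = (mean_pos - mean_neg) / diag_var
    intercept = (
        -0.5 * float(mean_pos @ (mean_pos / diag_var))
        + 0.5 * float(mean_neg @ (mean_neg / diag_var))
        + float(log_prior)
    )
    return coef, intercept


class DldaResults(DiscriminantResults):
    """Results of diagonal LDA: an affine score ``x @ coef + intercept``."""

    def __init__(self, model, threshold, train_scores, *, mean_neg, mean_pos,
                 diag_var, log_prior):
        self.mean_neg = mean_neg
        self.mean_pos = mean_pos
        self.diag_var = diag_var
        self.log_prior = float(log_prior)
        self.coef, self.intercept = dlda_affine_parameters(
            mean_neg, mean_pos, diag_var, log_prior)
        super().__init__(model, threshold, train_scores,
                         extra={"log_prior": self.log_prior})

    def _score_array(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef + self.intercept


class DiagonalLDA(DiscriminantModel):
    """Diagonal linear discriminant analysis.

    Parameters
    ----------
    variance : {'total', 'pooled_within'}
        'total' (default) uses the per-gene variance of the pooled training
        sample, both classes together; 'pooled_within' uses the class-size
        weighted within-class variance.
    variance_floor : float, optional
        Lower bound applied to per-gene variances; defaults to
        ``1e-8 * median(variance)`` to keep the score finite on degenerate
        genes. Floored genes are logged.
    """

    method = "dlda"

    def fit(self, variance: str = "total",
            variance_floor: float | None = None) -> DldaResults:
        X, y = self.X, self.y
        neg, pos = X[y == -1], X[y == 1]
        mean_neg = neg.mean(axis=0)
        mean_pos = pos.mean(axis=0)
        if variance == "total":
            var = X.var(axis=0, ddof=1)
        elif variance == "pooled_within":
            ss = ((neg - mean_neg) ** 2).sum(axis=0) + ((pos - mean_pos) ** 2).sum(axis=0)
            var = ss / (X.shape[0] - 2)
        else:
            raise ValueError("variance must be 'total' or 'pooled_within'")
        if variance_floor is None:
            med = float(np.median(var))
            variance_floor = 1e-8 * med if med > 0 else 1e-12
        n_floored = int((var < variance_floor).sum())
        if n_floored:
            logger.warning("flooring %d degenerate gene variances to %g",
                           n_floored, variance_floor)
        var = np.maximum(var, variance_floor)
        log_prior = float(np.log((y == 1).sum() / (y == -1).sum()))
        coef, intercept = dlda_affine_parameters(mean_neg, mean_pos, var, log_prior)
        scores = X @ coef + intercept
        threshold = select_threshold(scores, y)
        return DldaResults(self, threshold, scores, mean_neg=mean_neg,
                           mean_pos=mean_pos, diag_var=var, log_prior=log_prior)
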