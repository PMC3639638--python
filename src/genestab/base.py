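"""Model/Results base classes shared by all discriminant methods.

Every method follows the same two-object pattern: a model is constructed
from training data (expression matrix + phenotype table, optionally
restricted to a gene subset) and ``fit()`` returns a results object holding
the fitted parameters, the training-error-minimising decision threshold,
training metrics, and ``score`` / ``predict`` / ``evaluate`` / ``summary``
methods. Classification is ``y = +1`` iff ``score >= threshold``.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .data import ExpressionMatrix, PhenotypeTable
from .metrics import MetricReport, empirical_auc, error_rate

logger = logging.getLogger(__name__)

__all__ = ["DiscriminantModel", "DiscriminantResults", "select_threshold"]


def select_threshold(scores, labels) -> float:
    """Decision threshold minimising the training error rate.

    Candidates are the midpoints of consecutive sorted distinct scores plus
    one surrogate below the minimum and one above the maximum (the two
    trivial rules). Classification at exactly the threshold predicts +1.
    Ties in error are broken toward the candidate with the larger margin to
    the nearest score, then toward the smaller threshold value.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.size == 0:
        raise ValueError("no training scores")
    distinct = np.unique(s)
    candidates = [distinct[0] - 1.0]
    candidates.extend(0.5 * (distinct[:-1] + distinct[1:]))
    candidates.append(distinct[-1] + 1.0)
    best = None
    for c in candidates:
        err = error_rate(s, y, c)
        margin = float(np.min(np.abs(s - c)))
        key = (err, -margin, c)
        if best is None or key < best[0]:
            best = (key, c)
    return float(best[1])


class DiscriminantResults:
    """Fitted discriminant function with its threshold and diagnostics."""

    def __init__(
        self,
        model: "DiscriminantModel",
        threshold: float,
        train_scores: np.ndarray,
        extra: dict | None = None,
    ):
        self.model = model
        self.method = model.method
        self.gene_ids_used = list(model.gene_ids_used)
        self.threshold = float(threshold)
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        self.train_scores = np.asarray(train_scores, dtype=float)
        self.extra = extra or {}
        y = model.y
        self.train_report = MetricReport(
            auc=empirical_auc(self.train_scores[y == -1], self.train_scores[y == 1]),
            error_rate=error_rate(self.train_scores, y, self.threshold),
            n_pos=int((y == 1).sum()),
            n_neg=int((y == -1).sum()),
            dataset_tag="train",
        )

    # subclasses implement scoring on a raw (n, p_used) array
    def _score_array(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def score(self, expr: ExpressionMatrix) -> np.ndarray:
        """Discriminant scores for the samples of ``expr`` (uses only the
        genes the model was fitted on)."""
        X = expr.subset_genes(self.gene_ids_used).values
        return self._score_array(X)

    def predict(self, expr: ExpressionMatrix) -> np.ndarray:
        """Predicted labels in {-1, +1}; ``score >= threshold`` maps to +1."""
        return np.where(self.score(expr) >= self.threshold, 1, -1)

    def evaluate(
        self, expr: ExpressionMatrix, phen: PhenotypeTable, tag: str = "test"
    ) -> MetricReport:
        s = self.score(expr)
        y = phen.labels_for(expr.sample_ids)
        neg, pos = s[y == -1], s[y == 1]
        return MetricReport(
            auc=empirical_auc(neg, pos),
            error_rate=error_rate(s, y, self.threshold),
            n_pos=int(pos.size),
            n_neg=int(neg.size),
            dataset_tag=tag,
        )

    def summary(self) -> str:
        r = self.train_report
        lines = [
            f"{self.method} discriminant results",
            "=" * 40,
            f"genes used:       {len(self.gene_ids_used)}",
            f"n train (-/+):    {r.n_neg}/{r.n_pos}",
            f"threshold:        {self.threshold:.6g}",
            f"train AUC:        {r.auc:.4f}",
            f"train error rate: {r.error_rate:.4f}",
        ]
        for k, v in self.extra.items():
            if np.isscalar(v):
                lines.append(f"{k + ':':<18}{v}")
        return "\n".join(lines)


class DiscriminantModel:
    """Base model: training data restricted to a gene subset.

    Parameters
    ----------
    expr : ExpressionMatrix
        Training expression (samples x genes).
    phen : PhenotypeTable
        Paired outcomes; both classes must be present.
    genes : sequence of str, optional
        Gene subset to fit on (e.g. one sliding window); defaults to all.
    """

    method = "base"

    def __init__(
        self,
        expr: ExpressionMatrix,
        phen: PhenotypeTable,
        genes: Sequence[str] | None = None,
    ):
        phen.check_paired(expr)
        self.gene_ids_used = list(genes) if genes is not None else list(expr.gene_ids)
        self.X = expr.subset_genes(self.gene_ids_used).values
        self.y = phen.labels_for(expr.sample_ids)
        if len(np.unique(self.y)) < 2:
            raise ValueError("training data must contain both classes")
        self.n, self.p = self.X.shape

    def fit(self, **kwargs) -> DiscriminantResults:  # pragma: no cover
        raise NotImplementedError
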