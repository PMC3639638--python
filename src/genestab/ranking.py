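"""Gene ranking, sliding-window gene-set families, and resampling stability.

A signature is built by ranking genes on a univariate association with the
outcome (absolute Pearson correlation, or single-gene AUC folded as
``max(A, 1-A)``) and taking the top-k. The sliding-window family walks that
ranked list in overlapping windows (width 70, step 5 by default, the family
``D_{1-70}, D_{6-75}, ..., D_{161-230}`` over 230 ranked genes) so that each
window is an alternative candidate signature; evaluating every window with
every discriminant method shows how many gene sets predict almost equally
well. Resampling (50-of-78 subsamples, 100 draws by default) measures how
often each gene re-enters the top-k — the instability of the ranking itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, PhenotypeTable
from .metrics import MetricReport, empirical_auc
from .registry import METHODS

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRanking", "WindowFamily", "WindowEvaluation", "StabilityReport",
    "rank_genes", "build_windows", "evaluate_windows",
    "resample_stability", "resample_prediction",
]


@dataclass
class GeneRanking:
    """Genes ordered best-first with their association scores."""

    gene_ids: list[str]
    scores: pd.Series
    method: str

    def top(self, k: int) -> list[str]:
        return self.gene_ids[:k]


@dataclass
class WindowFamily:
    """Inclusive 1-based rank windows ``[1+(i-1)*step, width+(i-1)*step]``."""

    windows: list[tuple[int, int]]
    width: int
    step: int


@dataclass
class WindowEvaluation:
    """Train/test metrics of one method on one rank window."""

    window_index: int
    start_rank: int
    end_rank: int
    method: str
    train: MetricReport | None = None
    test: MetricReport | None = None
    error: str | None = None


@dataclass
class StabilityReport:
    """Top-k inclusion frequency of every gene over resamples."""

    inclusion_rate: pd.Series
    n_resamples: int
    subsample_size: int
    top_k: int
    method: str
    n_redraws: int = 0
    metric_per_resample: list[MetricReport] = field(default_factory=list)


def rank_genes(expr: ExpressionMatrix, phen: PhenotypeTable,
               method: str = "correlation", signed: bool = False) -> GeneRanking:
    """Rank genes by association with the outcome.

    'correlation': absolute Pearson correlation of each gene with y (signed
    ranking available via ``signed=True``); 'auc': per-gene AUC of the raw
    expression as a score, folded to ``max(A, 1-A)`` (half-tie convention).
    Constant genes score 0 and are logged. Ties keep input gene order.
    """
    phen.check_paired(expr)
    y = phen.labels_for(expr.sample_ids).astype(float)
    X = expr.values
    if method == "correlation":
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        denom = np.linalg.norm(Xc, axis=0) * np.linalg.norm(yc)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc.T @ yc) / denom
        const = ~np.isfinite(r)
        if const.any():
            logger.warning("%d constant genes scored 0 in ranking", const.sum())
        r[const] = 0.0
        score = r if signed else np.abs(r)
    elif method == "auc":
        neg = X[y == -1]
        pos = X[y == 1]
        score = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            a = empirical_auc(neg[:, j], pos[:, j], ties="half")
            score[j] = max(a, 1.0 - a)
    else:
        raise ValueError("ranking method must be 'correlation' or 'auc'")
    order = np.argsort(-score, kind="stable")
    gene_ids = [expr.gene_ids[j] for j in order]
    return GeneRanking(gene_ids, pd.Series(score, index=expr.gene_ids), method)


def build_windows(ranking: GeneRanking | int, width: int = 70, step: int = 5,
                  n_windows: int | None = None) -> WindowFamily:
    """Sliding windows down a ranking (by ranking object or its length)."""
    n_ranked = ranking if isinstance(ranking, int) else len(ranking.gene_ids)
    if step < 1:
        raise ValueError("step must be >= 1")
    if width < 1 or width > n_ranked:
        raise ValueError("width must be in [1, n_ranked]")
    if n_windows is None:
        n_windows = (n_ranked - width) // step + 1
    if n_windows < 1 or width + (n_windows - 1) * step > n_ranked:
        raise ValueError("window family overruns the ranking")
    windows = [(1 + i * step, width + i * step) for i in range(n_windows)]
    return WindowFamily(windows, width, step)


def evaluate_windows(
    family: WindowFamily,
    ranking: GeneRanking,
    train: tuple[ExpressionMatrix, PhenotypeTable],
    test: tuple[ExpressionMatrix, PhenotypeTable],
    methods=("vantveer", "dlda"),
    method_kwargs: dict | None = None,
) -> list[WindowEvaluation]:
    """Fit every method on every window's genes (training data only) and
    report train/test AUC and error rate; failures are recorded, not fatal."""
    method_kwargs = method_kwargs or {}
    expr_tr, phen_tr = train
    expr_te, phen_te = test
    out: list[WindowEvaluation] = []
    for i, (start, end) in enumerate(family.windows, start=1):
        genes = ranking.gene_ids[start - 1:end]
        for m in methods:
            ev = WindowEvaluation(i, start, end, m)
            try:
                model = METHODS[m](expr_tr, phen_tr, genes=genes)
                res = model.fit(**method_kwargs.get(m, {}))
                ev.train = res.train_report
                ev.test = res.evaluate(expr_te, phen_te, tag="test")
            except Exception as exc:  # noqa: BLE001 - recorded per spec
                ev.error = f"{type(exc).__name__}: {exc}"
                logger.warning("window %d method %s failed: %s", i, m, ev.error)
            out.append(ev)
    return out


def window_table(evaluations: list[WindowEvaluation]) -> pd.DataFrame:
    """Long-format table (window, method, split, auc, error_rate)."""
    rows = []
    for ev in evaluations:
        for split, rep in (("train", ev.train), ("test", ev.test)):
            rows.append({
                "window": ev.window_index,
                "start_rank": ev.start_rank,
                "end_rank": ev.end_rank,
                "method": ev.method,
                "split": split,
                "auc": rep.auc if rep else np.nan,
                "error_rate": rep.error_rate if rep else np.nan,
                "error": ev.error,
            })
    return pd.DataFrame(rows)


def _draw_subsample(rng, sample_ids, y, size, max_redraws=100):
    """Without-replacement subsample containing both classes (redraw if not)."""
    redraws = 0
    while True:
        idx = rng.choice(len(sample_ids), size=size, replace=False)
        if len(np.unique(y[idx])) == 2:
            return np.sort(idx), redraws
        redraws += 1
        if redraws >= max_redraws:
            raise ValueError(
                f"{max_redraws} consecutive single-class subsamples; "
                "subsample_size too small for the class balance"
            )


def resample_stability(
    expr: ExpressionMatrix,
    phen: PhenotypeTable,
    subsample_size: int = 50,
    n_resamples: int = 100,
    top_k: int = 70,
    method: str = "correlation",
    seed: int = 0,
) -> StabilityReport:
    """Top-k inclusion frequency of every gene over random subsamples.

    Each draw is a without-replacement subsample of patients; genes are
    re-ranked on the subsample and top-k membership recorded. Single-class
    draws are rejected and redrawn (logged).
    """
    phen.check_paired(expr)
    if not 0 < subsample_size <= expr.n_samples:
        raise ValueError("subsample_size must be in (0, n_samples]")
    y = phen.labels_for(expr.sample_ids)
    rng = np.random.default_rng(seed)
    counts = pd.Series(0.0, index=expr.gene_ids)
    total_redraws = 0
    for _ in range(n_resamples):
        idx, redraws = _draw_subsample(rng, expr.sample_ids, y, subsample_size)
        total_redraws += redraws
        ids = [expr.sample_ids[i] for i in idx]
        ranking = rank_genes(expr.subset_samples(ids), phen.subset(ids), method)
        counts[ranking.top(top_k)] += 1.0
    if total_redraws:
        logger.info("redrew %d single-class subsamples", total_redraws)
    return StabilityReport(counts / n_resamples, n_resamples, subsample_size,
                           top_k, method, n_redraws=total_redraws)


def resample_prediction(
    expr: ExpressionMatrix,
    phen: PhenotypeTable,
    subsample_size: int = 50,
    n_resamples: int = 100,
    top_k: int = 70,
    ranking_method: str = "correlation",
    classifier: str = "dlda",
    seed: int = 0,
    eval_pair: tuple[ExpressionMatrix, PhenotypeTable] | None = None,
    classifier_kwargs: dict | None = None,
) -> list[MetricReport]:
    """Distribution of AUC/error over resampled signature-building runs.

    Per resample: rank genes on the subsample, take the top-k, fit the
    classifier on the subsample, evaluate on the complement (default) or on
    a fixed external pair if ``eval_pair`` is given.
    """
    phen.check_paired(expr)
    y = phen.labels_for(expr.sample_ids)
    rng = np.random.default_rng(seed)
    kw = classifier_kwargs or {}
    reports: list[MetricReport] = []
    for rep in range(n_resamples):
        idx, _ = _draw_subsample(rng, expr.sample_ids, y, subsample_size)
        ids = [expr.sample_ids[i] for i in idx]
        sub_expr = expr.subset_samples(ids)
        sub_phen = phen.subset(ids)
        ranking = rank_genes(sub_expr, sub_phen, ranking_method)
        genes = ranking.top(top_k)
        model = METHODS[classifier](sub_expr, sub_phen, genes=genes)
        res = model.fit(**kw)
        if eval_pair is not None:
            ev_expr, ev_phen = eval_pair
        else:
            rest = [s for s in expr.sample_ids if s not in set(ids)]
            ev_expr = expr.subset_samples(rest)
            ev_phen = phen.subset(rest)
        if len(np.unique(ev_phen.labels_for(ev_expr.sample_ids))) < 2:
            logger.warning("resample %d: single-class evaluation set skipped", rep)
            continue
        reports.append(res.evaluate(ev_expr, ev_phen, tag=f"resample{rep}"))
    return reports
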