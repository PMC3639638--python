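"""Boosting discriminants: AdaBoost on decision stumps and AUCBoost on
natural-cubic-spline weak learners with a roughness penalty.

AdaBoost greedily minimises the exponential loss
``L(F) = (1/n) sum_i exp(-y_i F(x_i))`` over the dictionary of one-gene
decision stumps ``f_k(x) = +1 if x_k >= b_k else -1`` (cuts at midpoints of
consecutive distinct training values). Each round selects the stump with
weighted error farthest from 1/2 (both stump orientations are represented
implicitly through the sign of its coefficient), sets
``beta = 0.5 * log((1 - eps) / eps)`` and reweights multiplicatively; the
just-chosen stump's error under the updated weights is exactly 1/2.

AUCBoost maximises a Gaussian-smoothed AUC penalised by the integrated
squared second derivative of each gene's score component,

    obj(F) = smoothed AUC(F; sigma=1) - lambda * sum_k int F_k''(x)^2 dx.

Weak learners are standardized natural-cubic-spline basis functions of one
gene; each round takes a one-step Newton-Raphson coefficient from 0 for
every candidate and appends the candidate with the best penalised objective.
``(lambda, T)`` are selected jointly by stratified cross-validation on the
validation smoothed AUC, then the model is refitted on all training data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .base import DiscriminantModel, DiscriminantResults, select_threshold
from .data import ExpressionMatrix
from .metrics import smoothed_auc

logger = logging.getLogger(__name__)

__all__ = [
    "DecisionStump", "AdaBoost", "AdaBoostResults", "exp_loss",
    "build_stump_dictionary", "SplineLearner", "build_spline_dictionary",
    "natural_basis", "natural_basis_d2", "second_derivative_gram",
    "roughness_penalty", "AUCBoost", "AucBoostResults",
]


# ---------------------------------------------------------------------------
# decision stumps / AdaBoost

@dataclass(frozen=True)
class DecisionStump:
    """One-gene threshold classifier: +1 if ``x[gene] >= cut`` else -1."""

    gene_id: str
    cut: float

    def evaluate(self, xk: np.ndarray) -> np.ndarray:
        return np.where(np.asarray(xk) >= self.cut, 1, -1)


def _gene_cuts(values: np.ndarray) -> np.ndarray:
    distinct = np.unique(values)
    return 0.5 * (distinct[:-1] + distinct[1:])


def build_stump_dictionary(expr: ExpressionMatrix, genes=None) -> list[DecisionStump]:
    """All stumps over a gene subset: cuts at midpoints of consecutive sorted
    distinct training values. Constant genes contribute no stumps."""
    sub = expr.subset_genes(genes) if genes is not None else expr
    stumps: list[DecisionStump] = []
    for j, g in enumerate(sub.gene_ids):
        cuts = _gene_cuts(sub.values[:, j])
        if cuts.size == 0:
            logger.warning("gene %s is constant on the training data; no stumps", g)
        stumps.extend(DecisionStump(g, float(c)) for c in cuts)
    return stumps


def exp_loss(scores, labels) -> float:
    """Mean exponential loss ``(1/n) sum exp(-y F)`` (overflow-guarded)."""
    m = -np.asarray(labels, dtype=float) * np.asarray(scores, dtype=float)
    from scipy.special import logsumexp
    with np.errstate(over="ignore"):
        return float(np.exp(logsumexp(m) - np.log(m.size)))


class AdaBoostResults(DiscriminantResults):
    """Fitted stump ensemble ``F(x) = sum_t beta_t f_t(x)``."""

    def __init__(self, model, threshold, train_scores, rounds, history):
        self.rounds = rounds          # list of (DecisionStump, beta)
        self.history = history        # per-round diagnostics dicts
        super().__init__(model, threshold, train_scores,
                         extra={"rounds": len(rounds)})

    def _score_array(self, X: np.ndarray) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids_used)}
        F = np.zeros(X.shape[0])
        for stump, beta in self.rounds:
            F += beta * stump.evaluate(X[:, pos[stump.gene_id]])
        return F


class AdaBoost(DiscriminantModel):
    """AdaBoost over the exhaustive decision-stump dictionary.

    Ties in stump selection are broken toward the smallest gene index, then
    the smallest cut, making the fit invariant to sample ordering.
    """

    method = "adaboost"

    def fit(self, T: int = 100) -> AdaBoostResults:
        if T < 1:
            raise ValueError("T must be >= 1")
        X, y, n = self.X, self.y, self.n
        stump_gene: list[int] = []
        stump_cut: list[float] = []
        for j in range(self.p):
            for c in _gene_cuts(X[:, j]):
                stump_gene.append(j)
                stump_cut.append(float(c))
        if not stump_gene:
            raise ValueError("all genes constant; empty stump dictionary")
        gene_idx = np.array(stump_gene)
        cuts = np.array(stump_cut)
        # stump prediction matrix, ordered by gene index then cut
        P = np.where(X[:, gene_idx] >= cuts[None, :], 1, -1).T.astype(np.int8)
        mis = (P != y[None, :])
        w = np.full(n, 1.0 / n)
        clip_lo, clip_hi = 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)
        rounds, history = [], []
        F = np.zeros(n)
        for _ in range(T):
            eps_all = mis @ w / w.sum()
            sel = int(np.argmax(np.abs(eps_all - 0.5)))  # first max: gene, then cut
            eps = float(eps_all[sel])
            eps_c = min(max(eps, clip_lo), clip_hi)
            if eps_c != eps:
                logger.warning("clipping weighted error %g to %g", eps, eps_c)
            beta = 0.5 * np.log((1.0 - eps_c) / eps_c)
            f = P[sel].astype(float)
            w = w * np.exp(-y * beta * f)
            w = w / w.sum()
            F = F + beta * f
            rounds.append(
                (DecisionStump(self.gene_ids_used[gene_idx[sel]], float(cuts[sel])),
                 float(beta))
            )
            history.append({
                "eps": eps,
                "eps_clipped": eps_c,
                "beta": float(beta),
                "loss": exp_loss(F, y),
                "reweighted_error": float(mis[sel] @ w),
            })
        threshold = select_threshold(F, y)
        return AdaBoostResults(self, threshold, F, rounds, history)


# ---------------------------------------------------------------------------
# natural cubic splines

def natural_basis(x, knots: np.ndarray) -> np.ndarray:
    """Natural-cubic-spline basis matrix with ``m = len(knots)`` columns.

    Column 0 is the constant, column 1 the identity, columns ``l+2`` the
    truncated-power combinations ``d_l - d_{m-2}`` that are linear beyond the
    boundary knots. The spanned space is the full m-dimensional natural
    cubic spline space on these knots.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    m = knots.size
    N = np.empty((x.size, m))
    N[:, 0] = 1.0
    N[:, 1] = x

    def d(k):
        return (
            np.clip(x - knots[k], 0, None) ** 3
            - np.clip(x - knots[-1], 0, None) ** 3
        ) / (knots[-1] - knots[k])

    if m > 2:
        dm1 = d(m - 2)
        for l in range(m - 2):
            N[:, l + 2] = d(l) - dm1
    return N


def natural_basis_d2(x, knots: np.ndarray) -> np.ndarray:
    """Second derivatives of :func:`natural_basis` (piecewise linear in x,
    identically zero outside the boundary knots)."""
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    m = knots.size
    D = np.zeros((x.size, m))

    def dd(k):
        return 6.0 * (
            np.clip(x - knots[k], 0, None) - np.clip(x - knots[-1], 0, None)
        ) / (knots[-1] - knots[k])

    if m > 2:
        ddm1 = dd(m - 2)
        for l in range(m - 2):
            D[:, l + 2] = dd(l) - ddm1
    return D


def second_derivative_gram(knots: np.ndarray) -> np.ndarray:
    """Exact Gram matrix ``int N_a'' N_b'' dx`` over the knot range.

    Second derivatives are piecewise linear between knots, so a per-interval
    Simpson rule (exact for quadratics) gives the closed form.
    """
    knots = np.asarray(knots, dtype=float)
    m = knots.size
    omega = np.zeros((m, m))
    for a, b in zip(knots[:-1], knots[1:]):
        pts = np.array([a, 0.5 * (a + b), b])
        wts = (b - a) / 6.0 * np.array([1.0, 4.0, 1.0])
        D = natural_basis_d2(pts, knots)
        omega += D.T @ (wts[:, None] * D)
    return omega


@dataclass(frozen=True)
class SplineLearner:
    """One standardized spline basis function of one gene.

    ``basis_index`` indexes :func:`natural_basis` columns (1 = linear part);
    the constant column is never a learner. ``standardization`` divides the
    basis so the learner has unit standard deviation on the training sample.
    """

    gene_id: str
    basis_index: int
    knots: tuple[float, ...]
    standardization: float

    def evaluate(self, xk) -> np.ndarray:
        N = natural_basis(xk, np.asarray(self.knots))
        return N[:, self.basis_index] / self.standardization

    def d2(self, xk) -> np.ndarray:
        D = natural_basis_d2(xk, np.asarray(self.knots))
        return D[:, self.basis_index] / self.standardization


def _gene_learners(values: np.ndarray, gene_id: str, n_knots: int):
    """Spline learners for one gene; linear-only fallback when the gene has
    too few distinct values for the requested knots."""
    distinct = np.unique(values)
    if distinct.size < 2:
        logger.warning("gene %s constant; no spline learners", gene_id)
        return []
    if distinct.size < max(n_knots, 3):
        logger.warning("gene %s has %d distinct values; linear fallback",
                       gene_id, distinct.size)
        knots = np.array([distinct[0], distinct[-1]])
        basis_indices = [1]
    else:
        qs = np.arange(1, n_knots + 1) / (n_knots + 1)
        knots = np.unique(np.quantile(values, qs))
        if knots.size < 3:
            knots = np.array([distinct[0], distinct[-1]])
            basis_indices = [1]
        else:
            basis_indices = list(range(1, knots.size))
    N = natural_basis(values, knots)
    learners = []
    for l in basis_indices:
        z = float(N[:, l].std())
        if z == 0:
            logger.warning("gene %s basis %d degenerate on training data", gene_id, l)
            continue
        learners.append(SplineLearner(gene_id, l, tuple(knots), z))
    return learners


def build_spline_dictionary(expr: ExpressionMatrix, genes=None,
                            n_knots: int = 5) -> list[SplineLearner]:
    """Standardized natural-spline learners for each gene (knots at equally
    spaced quantiles of the training values)."""
    if n_knots < 3:
        raise ValueError("n_knots must be >= 3")
    sub = expr.subset_genes(genes) if genes is not None else expr
    learners: list[SplineLearner] = []
    for j, g in enumerate(sub.gene_ids):
        learners.extend(_gene_learners(sub.values[:, j], g, n_knots))
    return learners


def roughness_penalty(learners: list[SplineLearner], coeffs) -> float:
    """Integrated squared second derivative of one gene's component
    ``F_k = sum_l c_l * learner_l`` (all learners must share gene and knots)."""
    coeffs = np.asarray(coeffs, dtype=float)
    if not learners:
        return 0.0
    if len({(lr.gene_id, lr.knots) for lr in learners}) != 1:
        raise ValueError("learners must share one gene and one knot set")
    omega = second_derivative_gram(np.asarray(learners[0].knots))
    idx = [lr.basis_index for lr in learners]
    z = np.array([lr.standardization for lr in learners])
    sub = omega[np.ix_(idx, idx)] / np.outer(z, z)
    return float(coeffs @ sub @ coeffs)


# ---------------------------------------------------------------------------
# AUCBoost

class AucBoostResults(DiscriminantResults):
    """Fitted spline ensemble with its selected smoothing parameter."""

    def __init__(self, model, threshold, train_scores, rounds, lam, T,
                 cv_table=None):
        self.rounds = rounds          # list of (SplineLearner, beta)
        self.lambda_ = float(lam)
        self.sigma = 1.0
        self.n_rounds = int(T)
        self.cv_table = cv_table      # DataFrame-like dict of CV results
        super().__init__(model, threshold, train_scores,
                         extra={"lambda": lam, "rounds": T})

    def _score_array(self, X: np.ndarray) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids_used)}
        F = np.zeros(X.shape[0])
        for lr, beta in self.rounds:
            F += beta * lr.evaluate(X[:, pos[lr.gene_id]])
        return F

    def component_coefficients(self) -> dict[str, tuple[list[SplineLearner], np.ndarray]]:
        """Per-gene component: distinct learners and their summed coefficients."""
        comp: dict[str, dict[SplineLearner, float]] = {}
        for lr, beta in self.rounds:
            comp.setdefault(lr.gene_id, {})
            comp[lr.gene_id][lr] = comp[lr.gene_id].get(lr, 0.0) + beta
        return {
            g: (list(d.keys()), np.array(list(d.values())))
            for g, d in comp.items()
        }

    def component_roughness(self, gene_id: str) -> float:
        comp = self.component_coefficients()
        if gene_id not in comp:
            return 0.0
        learners, coeffs = comp[gene_id]
        return roughness_penalty(learners, coeffs)

    def total_roughness(self) -> float:
        return sum(self.component_roughness(g) for g in self.component_coefficients())


_FALLBACK_STEPS = np.array([-1.0, -0.5, -0.1, 0.1, 0.5, 1.0])


class _AucBoostEngine:
    """One boosting run at fixed lambda on a fixed learner dictionary."""

    def __init__(self, learners, V, y, lam):
        self.learners = learners
        self.lam = lam
        self.y = y
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == -1)
        self.n_pairs = pos_idx.size * neg_idx.size
        # pairwise learner differences: (n_pairs, L)
        self.dV = (V[pos_idx][:, None, :] - V[neg_idx][None, :, :]).reshape(
            self.n_pairs, V.shape[1])
        self.dF = np.zeros(self.n_pairs)
        # per-gene penalty bookkeeping on normalized learners
        self.gene_of = {}
        gene_cols: dict[str, list[int]] = {}
        for col, lr in enumerate(learners):
            gene_cols.setdefault(lr.gene_id, []).append(col)
        self.gene_cols = gene_cols
        self.quad = np.zeros(len(learners))       # diag of per-gene Gram
        self.grams = {}
        for g, cols in gene_cols.items():
            lrs = [learners[c] for c in cols]
            omega = second_derivative_gram(np.asarray(lrs[0].knots))
            idx = [lr.basis_index for lr in lrs]
            z = np.array([lr.standardization for lr in lrs])
            gram = omega[np.ix_(idx, idx)] / np.outer(z, z)
            self.grams[g] = gram
            self.quad[cols] = np.diag(gram)
        self.coeffs = np.zeros(len(learners))
        self.penalty = 0.0
        self.n_fallback = 0

    def _cross(self) -> np.ndarray:
        cross = np.zeros(len(self.learners))
        for g, cols in self.gene_cols.items():
            c = self.coeffs[cols]
            if np.any(c):
                cross[cols] = self.grams[g] @ c
        return cross

    def step(self) -> tuple[int, float]:
        """One boosting round; returns (selected column, beta)."""
        lam, dV, dF = self.lam, self.dV, self.dF
        npairs = self.n_pairs
        phi = norm.pdf(dF)
        cross = self._cross()
        grad = (phi @ dV) / npairs - 2.0 * lam * cross
        curv = ((phi * (-dF)) @ (dV ** 2)) / npairs - 2.0 * lam * self.quad
        beta = np.zeros_like(grad)
        ok = curv < -1e-12
        beta[ok] = -grad[ok] / curv[ok]
        # penalised objective at the per-candidate beta
        obj = self._objective(beta, cross)
        if np.any(~ok):
            self.n_fallback += int((~ok).sum())
            best_fb = np.full(grad.size, -np.inf)
            best_fb_beta = np.zeros(grad.size)
            for b in _FALLBACK_STEPS:
                o = self._objective(np.full(grad.size, b), cross)
                better = o > best_fb
                best_fb[better] = o[better]
                best_fb_beta[better] = b
            obj[~ok] = best_fb[~ok]
            beta[~ok] = best_fb_beta[~ok]
        sel = int(np.argmax(obj))
        b = float(beta[sel])
        self.dF = dF + b * dV[:, sel]
        self.coeffs[sel] += b
        self.penalty = self._current_penalty()
        return sel, b

    def _current_penalty(self) -> float:
        total = 0.0
        for g, cols in self.gene_cols.items():
            c = self.coeffs[cols]
            if np.any(c):
                total += float(c @ self.grams[g] @ c)
        return total

    def _objective(self, beta: np.ndarray, cross: np.ndarray) -> np.ndarray:
        sauc = norm.cdf(self.dF[:, None] + self.dV * beta[None, :]).mean(axis=0)
        pen = self.penalty + 2.0 * beta * cross + beta ** 2 * self.quad
        return sauc - self.lam * pen

    def objective_value(self) -> float:
        return float(norm.cdf(self.dF).mean()) - self.lam * self.penalty


class AUCBoost(DiscriminantModel):
    """Penalised smoothed-AUC boosting with natural-cubic-spline learners.

    ``fit`` selects ``(lambda, T)`` jointly by stratified k-fold
    cross-validation on the validation smoothed AUC (sigma fixed at 1), then
    refits on the full training sample.
    """

    method = "aucboost"

    def fit(
        self,
        lambda_grid=(1e-3, 1e-2, 1e-1, 1.0, 10.0),
        T_max: int = 20,
        cv_folds: int = 5,
        n_knots: int = 5,
        seed: int = 0,
    ) -> AucBoostResults:
        if T_max < 1:
            raise ValueError("T_max must be >= 1")
        y = self.y
        expr_like = ExpressionMatrix(self.X, [f"i{i}" for i in range(self.n)],
                                     self.gene_ids_used)
        lambda_grid = list(lambda_grid)
        if len(lambda_grid) > 1 or cv_folds > 1:
            folds = _stratified_folds(y, cv_folds, np.random.default_rng(seed))
        else:
            folds = []
        cv_mean = {}
        if folds:
            paths = {lam: [] for lam in lambda_grid}
            for tr_idx, va_idx in folds:
                Xtr, ytr = self.X[tr_idx], y[tr_idx]
                Xva, yva = self.X[va_idx], y[va_idx]
                sub = ExpressionMatrix(Xtr, [f"t{i}" for i in range(len(tr_idx))],
                                       self.gene_ids_used)
                learners = build_spline_dictionary(sub, n_knots=n_knots)
                if not learners:
                    raise ValueError("empty spline dictionary on a CV fold")
                Vtr = np.column_stack([
                    lr.evaluate(Xtr[:, self._col(lr.gene_id)]) for lr in learners])
                Vva = np.column_stack([
                    lr.evaluate(Xva[:, self._col(lr.gene_id)]) for lr in learners])
                for lam in lambda_grid:
                    eng = _AucBoostEngine(learners, Vtr, ytr, lam)
                    Fva = np.zeros(len(va_idx))
                    path = []
                    for _ in range(T_max):
                        sel, b = eng.step()
                        Fva = Fva + b * Vva[:, sel]
                        path.append(smoothed_auc(Fva[yva == -1], Fva[yva == 1], 1.0))
                    paths[lam].append(path)
            for lam in lambda_grid:
                cv_mean[lam] = np.mean(paths[lam], axis=0)
            best_lam, best_t, best_val = None, None, -np.inf
            for lam in lambda_grid:
                for t in range(T_max):
                    if cv_mean[lam][t] > best_val:
                        best_val, best_lam, best_t = cv_mean[lam][t], lam, t + 1
        else:
            best_lam, best_t = lambda_grid[0], T_max

        learners = build_spline_dictionary(expr_like, n_knots=n_knots)
        if not learners:
            raise ValueError("empty spline dictionary")
        V = np.column_stack([
            lr.evaluate(self.X[:, self._col(lr.gene_id)]) for lr in learners])
        eng = _AucBoostEngine(learners, V, y, best_lam)
        rounds = []
        F = np.zeros(self.n)
        objective_path = []
        for _ in range(best_t):
            sel, b = eng.step()
            rounds.append((learners[sel], b))
            F = F + b * V[:, sel]
            objective_path.append(eng.objective_value())
        threshold = select_threshold(F, y)
        res = AucBoostResults(self, threshold, F, rounds, best_lam, best_t,
                              cv_table=cv_mean or None)
        res.objective_path = objective_path
        res.n_newton_fallbacks = eng.n_fallback
        return res

    def _col(self, gene_id: str) -> int:
        if not hasattr(self, "_colmap"):
            self._colmap = {g: i for i, g in enumerate(self.gene_ids_used)}
        return self._colmap[gene_id]


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator):
    """Class-stratified k-fold index pairs; every fold keeps both classes."""
    folds_of = np.empty(y.size, dtype=int)
    for cls in (-1, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        folds_of[idx] = np.arange(idx.size) % k
    out = []
    for f in range(k):
        va = np.flatnonzero(folds_of == f)
        tr = np.flatnonzero(folds_of != f)
        if len(np.unique(y[tr])) < 2 or va.size == 0:
            raise ValueError("fold without both classes; reduce cv_folds")
        if len(np.unique(y[va])) < 2:
            raise ValueError("validation fold lacks a class; reduce cv_folds")
        out.append((tr, va))
    return out
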