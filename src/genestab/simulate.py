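"""Synthetic expression studies with subtype and block-correlation structure.

The generator emulates the statistical shape of a two-class prognostic
microarray study: latent tumour subtypes drive both blocks of co-expressed
genes and hormone-receptor status; a minority of genes carries a weak mean
shift between outcome classes; genes inside a block share an equicorrelated
Gaussian factor, so the gene list contains many nearly interchangeable
columns — the regime in which correlation-ranked signatures are unstable and
mutual coherence is high.

Generative model, per sample i:

* subtype ``s_i`` ~ uniform categorical over ``n_subtypes``; subtype 0 is the
  poor-prognosis subtype with ``P(y=+1)=0.8``; the other subtypes share a rate
  solved from the requested marginal ``class_balance``.
* gene j in block b: ``z_ij = sqrt(rho) * u_ib + sqrt(1-rho) * e_ij`` with
  ``u, e`` iid standard normal (equicorrelation ``rho`` within the block);
  unassigned genes are plain ``e_ij``.
* mean structure (all in noise-SD units): informative genes add
  ``y_i * effect_size / 2``; block genes add a block-by-subtype offset drawn
  once from ``N(0, subtype_effect^2)`` so clustering by expression can recover
  subtypes.
* ER/PR status equals the subtype's nominal status (subtype 0 negative,
  others positive), flipped independently with probability
  ``1 - hormone_coupling``.

Everything is reproducible bit-for-bit from ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, PhenotypeTable

__all__ = ["SyntheticConfig", "GeneratedStudy", "GenerationError",
           "generate_study", "inject_collinear_pair"]


class GenerationError(ValueError):
    """Raised for configurations that cannot produce a valid study."""


POOR_SUBTYPE_POS_RATE = 0.8  # P(y=+1) in the poor-prognosis subtype


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generative model (defaults are the study conditions:
    97 patients as in a 78-train/19-test design, blocks of highly correlated
    genes, and a diffuse weak outcome signal)."""

    n_samples: int = 97
    n_genes: int = 300
    n_subtypes: int = 3
    block_sizes: tuple[int, ...] = (10,) * 20
    within_block_rho: float = 0.9
    n_informative: int = 90
    effect_size: float = 0.6
    class_balance: float = 0.4
    hormone_coupling: float = 0.9
    noise_sd: float = 1.0
    subtype_effect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_genes < 1:
            raise GenerationError("need at least 2 samples and 1 gene")
        if self.n_subtypes < 1:
            raise GenerationError("n_subtypes must be >= 1")
        if any(b <= 0 for b in self.block_sizes):
            raise GenerationError("block sizes must be positive")
        if sum(self.block_sizes) > self.n_genes:
            raise GenerationError("block sizes exceed n_genes")
        if not 0 <= self.within_block_rho < 1:
            raise GenerationError("within_block_rho must be in [0, 1)")
        if not 0 <= self.n_informative <= self.n_genes:
            raise GenerationError("n_informative must be in [0, n_genes]")
        if self.effect_size < 0:
            raise GenerationError("effect_size must be >= 0")
        if not 0 < self.class_balance < 1:
            raise GenerationError("class_balance must be in (0, 1)")
        if not 0 <= self.hormone_coupling <= 1:
            raise GenerationError("hormone_coupling must be in [0, 1]")
        if self.noise_sd <= 0:
            raise GenerationError("noise_sd must be > 0")

    def positive_rates(self) -> np.ndarray:
        """Per-subtype P(y=+1) matching the requested marginal balance."""
        s = self.n_subtypes
        if s == 1:
            return np.array([self.class_balance])
        other = (s * self.class_balance - POOR_SUBTYPE_POS_RATE) / (s - 1)
        if not 0.0 <= other <= 1.0:
            raise GenerationError(
                f"class_balance {self.class_balance} unreachable with "
                f"{s} subtypes (non-poor subtype rate {other:.3f})"
            )
        return np.array([POOR_SUBTYPE_POS_RATE] + [other] * (s - 1))


@dataclass
class GeneratedStudy:
    """A generated study plus its ground truth."""

    expression: ExpressionMatrix
    phenotypes: PhenotypeTable
    informative_gene_ids: set[str]
    block_assignment: dict[str, int | None]
    config: SyntheticConfig = field(repr=False)


def _block_index(config: SyntheticConfig) -> np.ndarray:
    """-1 for unassigned genes, else block index; genes fill blocks in order."""
    idx = np.full(config.n_genes, -1, dtype=int)
    start = 0
    for b, size in enumerate(config.block_sizes):
        idx[start:start + size] = b
        start += size
    return idx


def generate_study(config: SyntheticConfig, seed: int | None = None) -> GeneratedStudy:
    """Draw one study from the generative model.

    ``seed`` overrides ``config.seed`` when given. Raises
    :class:`GenerationError` when a drawn outcome vector is single-class.
    """
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    n, p, s = config.n_samples, config.n_genes, config.n_subtypes

    subtype = rng.integers(0, s, size=n)
    rates = config.positive_rates()
    y = np.where(rng.random(n) < rates[subtype], 1, -1)
    if len(np.unique(y)) < 2:
        raise GenerationError(
            "drawn outcome vector is single-class; increase n_samples or "
            "move class_balance away from the boundary"
        )

    eps = rng.standard_normal((n, p))
    block_idx = _block_index(config)
    n_blocks = len(config.block_sizes)
    z = eps.copy()
    if n_blocks:
        factors = rng.standard_normal((n, n_blocks))
        rho = config.within_block_rho
        in_block = block_idx >= 0
        z[:, in_block] = (
            np.sqrt(rho) * factors[:, block_idx[in_block]]
            + np.sqrt(1.0 - rho) * eps[:, in_block]
        )

    informative = rng.choice(p, size=config.n_informative, replace=False)
    mean = np.zeros((n, p))
    mean[:, informative] += (config.effect_size / 2.0) * y[:, None]

    if n_blocks and config.subtype_effect > 0:
        offsets = rng.standard_normal((n_blocks, s)) * config.subtype_effect
        in_block = block_idx >= 0
        mean[:, in_block] += offsets[block_idx[in_block], :][:, subtype].T

    values = config.noise_sd * (z + mean)

    nominal = (subtype != 0).astype(int)  # poor-prognosis subtype is ER/PR negative
    er = np.where(rng.random(n) < config.hormone_coupling, nominal, 1 - nominal)
    pr = np.where(rng.random(n) < config.hormone_coupling, nominal, 1 - nominal)

    width_s = len(str(n))
    width_g = len(str(p))
    sample_ids = [f"s{i + 1:0{width_s}d}" for i in range(n)]
    gene_ids = [f"g{j + 1:0{width_g}d}" for j in range(p)]
    expr = ExpressionMatrix(values, sample_ids, gene_ids)
    phen = PhenotypeTable(
        pd.Series(y, index=sample_ids),
        er=pd.Series(er, index=sample_ids),
        pr=pd.Series(pr, index=sample_ids),
        subtype=pd.Series(subtype, index=sample_ids),
    )
    blocks = {
        g: (int(block_idx[j]) if block_idx[j] >= 0 else None)
        for j, g in enumerate(gene_ids)
    }
    return GeneratedStudy(
        expression=expr,
        phenotypes=phen,
        informative_gene_ids={gene_ids[j] for j in informative},
        block_assignment=blocks,
        config=config,
    )


def inject_collinear_pair(
    study: GeneratedStudy,
    gene_a: str,
    gene_b: str,
    target_r: float,
) -> GeneratedStudy:
    """Rewrite ``gene_b`` as a ``target_r``-correlated mixture of ``gene_a``.

    The fresh-noise component is orthogonalised against ``gene_a`` so the
    empirical correlation equals ``target_r`` exactly (up to rounding); the
    new column keeps ``gene_b``'s original mean and SD. Useful as a fixture
    for near-duplicate genes and mutual-coherence checks.
    """
    if gene_a == gene_b:
        raise ValueError("gene_a and gene_b must differ")
    if not -1.0 <= target_r <= 1.0:
        raise ValueError("target_r must be in [-1, 1]")
    expr = study.expression
    ja, jb = expr.gene_indices([gene_a, gene_b])
    rng = np.random.default_rng([study.config.seed, 10007])
    xa = expr.values[:, ja]
    xb = expr.values[:, jb]
    a_std = (xa - xa.mean()) / xa.std()
    noise = rng.standard_normal(expr.n_samples)
    noise = noise - noise.mean()
    noise -= (noise @ a_std) / (a_std @ a_std) * a_std  # exact orthogonality
    norm = np.linalg.norm(noise)
    if norm == 0:  # pragma: no cover - degenerate tiny-n draw
        raise GenerationError("degenerate noise draw; cannot orthogonalise")
    noise /= noise.std()
    mixed = target_r * a_std + np.sqrt(max(0.0, 1.0 - target_r**2)) * noise
    new_b = xb.mean() + xb.std() * mixed / mixed.std()
    values = expr.values.copy()
    values[:, jb] = new_b
    new_expr = ExpressionMatrix(values, expr.sample_ids, expr.gene_ids)
    return GeneratedStudy(
        expression=new_expr,
        phenotypes=study.phenotypes,
        informative_gene_ids=set(study.informative_gene_ids),
        block_assignment=dict(study.block_assignment),
        config=study.config,
    )
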