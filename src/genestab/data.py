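"""Core tabular containers for expression studies.

An expression study is a real-valued ``samples x genes`` matrix of
(log-ratio) expression values paired with a per-sample phenotype table:
a binary outcome ``y`` coded ``-1`` (good prognosis) / ``+1`` (metastasis)
and, optionally, estrogen- and progesterone-receptor statuses and a latent
subtype label (synthetic studies only).

Files are plain TSV (tab-delimited, UTF-8, '.' decimal): expression files
carry a header row of gene identifiers and sample identifiers in the first
column; phenotype files carry columns ``sample_id``, ``y`` and optionally
``er``, ``pr``, ``subtype``. Missing values are rejected, never imputed —
the pipeline expects an already-filtered matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "PhenotypeTable",
    "FormatError",
    "DegenerateSplitError",
    "read_expression",
    "write_expression",
    "read_phenotypes",
    "write_phenotypes",
    "train_test_split",
]


class FormatError(ValueError):
    """Raised when an input file violates the tabular contract."""


class DegenerateSplitError(ValueError):
    """Raised when a training split would contain a single outcome class."""


def _check_unique(ids, what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """A ``samples x genes`` real matrix with sample and gene identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_genes)
        Unitless log-expression values; must be finite.
    sample_ids, gene_ids : sequence of str
        Unique ordered identifiers for rows and columns respectively.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.gene_ids):
            raise FormatError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} sample ids / {len(self.gene_ids)} gene ids"
            )
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.gene_ids, "gene id")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def gene_indices(self, gene_ids) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([pos[g] for g in gene_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"unknown gene id {exc.args[0]!r}") from None

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = self.gene_indices(gene_ids)
        return ExpressionMatrix(self.values[:, idx], self.sample_ids, list(gene_ids))

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return ExpressionMatrix(self.values[idx, :], list(sample_ids), self.gene_ids)


@dataclass
class PhenotypeTable:
    """Per-sample outcome labels plus optional hormone statuses and subtype.

    ``y`` maps sample id to -1 (good prognosis) or +1 (metastasis); ``er`` and
    ``pr`` map to 0/1 receptor status; ``subtype`` is the synthetic-truth
    latent subtype index where known.
    """

    y: pd.Series
    er: pd.Series | None = None
    pr: pd.Series | None = None
    subtype: pd.Series | None = None

    def __post_init__(self) -> None:
        self.y = pd.Series(self.y).astype(int)
        self.y.index = self.y.index.astype(str)
        _check_unique(list(self.y.index), "sample id")
        bad = set(self.y.unique()) - {-1, 1}
        if bad:
            raise FormatError(
                f"outcome y must be coded -1/+1, found {sorted(bad)}; "
                "recode explicitly before loading"
            )
        for name in ("er", "pr", "subtype"):
            s = getattr(self, name)
            if s is not None:
                s = pd.Series(s).astype(int)
                s.index = s.index.astype(str)
                if name in ("er", "pr") and not set(s.unique()) <= {0, 1}:
                    raise FormatError(f"{name} status must be 0/1")
                setattr(self, name, s)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.y.index)

    @property
    def n_pos(self) -> int:
        return int((self.y == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.y == -1).sum())

    def labels_for(self, sample_ids) -> np.ndarray:
        """Outcome vector aligned to ``sample_ids`` (raises on missing)."""
        return self.y.loc[list(sample_ids)].to_numpy()

    def subset(self, sample_ids) -> "PhenotypeTable":
        ids = list(sample_ids)
        return PhenotypeTable(
            self.y.loc[ids],
            None if self.er is None else self.er.loc[ids],
            None if self.pr is None else self.pr.loc[ids],
            None if self.subtype is None else self.subtype.loc[ids],
        )

    def check_paired(self, expr: ExpressionMatrix) -> None:
        missing = set(expr.sample_ids) - set(self.y.index)
        if missing:
            raise FormatError(f"samples missing from phenotype table: {sorted(missing)[:5]}")


def read_expression(path) -> ExpressionMatrix:
    """Read a ``samples x genes`` expression TSV, preserving file order."""
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "gene id (column)")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    _check_unique(list(df.index.astype(str)), "sample id (row)")
    try:
        values = df.to_numpy(dtype=str).astype(float)
    except ValueError:
        arr = df.to_numpy(dtype=str)
        for i in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                try:
                    float(arr[i, j])
                except ValueError:
                    raise FormatError(
                        f"non-numeric cell {arr[i, j]!r} at sample "
                        f"{df.index[i]!r}, gene {df.columns[j]!r}"
                    ) from None
        raise  # pragma: no cover - unreachable
    return ExpressionMatrix(values, list(df.index.astype(str)), list(df.columns))


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


_PHEN_COLUMNS = ("y", "er", "pr", "subtype")


def read_phenotypes(path) -> PhenotypeTable:
    """Read a phenotype TSV (columns sample_id, y[, er, pr, subtype])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "y" not in df.columns:
        raise FormatError("phenotype file needs 'sample_id' and 'y' columns")
    extra = [c for c in df.columns if c not in _PHEN_COLUMNS + ("sample_id",)]
    if extra:
        logger.warning("ignoring unknown phenotype columns: %s", extra)
    df = df.set_index("sample_id")
    try:
        y = df["y"].astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer outcome value: {exc}") from None
    kwargs = {}
    for name in ("er", "pr", "subtype"):
        if name in df.columns:
            kwargs[name] = df[name].astype(int)
    return PhenotypeTable(y, **kwargs)


def write_phenotypes(phen: PhenotypeTable, path) -> None:
    cols = {"y": phen.y}
    for name in ("er", "pr", "subtype"):
        s = getattr(phen, name)
        if s is not None:
            cols[name] = s
    pd.DataFrame(cols).to_csv(path, sep="\t", index_label="sample_id")


def train_test_split(
    expr: ExpressionMatrix,
    phen: PhenotypeTable,
    n_train: int,
    seed: int,
):
    """Randomly partition a study into train/test pairs.

    Deterministic given ``seed``; the split is disjoint and exhaustive.
    Raises :class:`DegenerateSplitError` if the training part would contain a
    single outcome class.
    """
    phen.check_paired(expr)
    n = expr.n_samples
    if not 0 < n_train < n:
        raise ValueError(f"n_train must be in (0, {n}), got {n_train}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    tr_ids = [expr.sample_ids[i] for i in sorted(order[:n_train])]
    te_ids = [expr.sample_ids[i] for i in sorted(order[n_train:])]
    y_tr = phen.labels_for(tr_ids)
    if len(np.unique(y_tr)) < 2:
        raise DegenerateSplitError("training split contains a single class")
    return (
        (expr.subset_samples(tr_ids), phen.subset(tr_ids)),
        (expr.subset_samples(te_ids), phen.subset(te_ids)),
    )
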