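"""Gene-expression preprocessing: filtering, KNN imputation, summaries, correlation.

Expression data enters as a genes x samples matrix of log2 ratios with
missing entries (two-channel microarray dropouts).  The pipeline keeps only
genes with few missing values, fills the remainder by K-nearest-neighbour
imputation, and computes pairwise Pearson correlations that the network
builder turns into edge weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSummary",
    "UndefinedCorrelationError",
    "read_expression_tsv",
    "write_expression_tsv",
    "filter_missing",
    "impute_knn",
    "summarize_gene",
    "pairwise_correlation",
    "evaluate_imputation_rmse",
]


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (too few shared samples or zero variance)."""


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2 expression ratios with a missingness mask.

    ``values[i, j]`` carries no meaning where ``mask[i, j]`` is True.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    mask: np.ndarray

    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values shape")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def observed(self, gene: str) -> np.ndarray:
        """Observed (unmasked) values of one gene."""
        i = self.row(gene)
        return self.values[i, ~self.mask[i]]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids), list(self.sample_ids), self.values.copy(), self.mask.copy()
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        values = df.to_numpy(dtype=float)
        mask = np.isnan(values)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), values, mask)

    def to_dataframe(self) -> pd.DataFrame:
        values = self.values.copy()
        values[self.mask] = np.nan
        return pd.DataFrame(values, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class GeneSummary:
    """Median log2 ratio of a gene and its over/under expression call."""

    gene_id: str
    median_log2: float
    call: str  # "over" or "under"


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a TSV with gene ids in the first column, sample ids in the header.

    Empty cells and ``NA`` denote missing values.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    return ExpressionMatrix.from_dataframe(df)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t", na_rep="NA")


def filter_missing(matrix: ExpressionMatrix, max_missing_frac: float = 0.2) -> ExpressionMatrix:
    """Keep genes whose missing fraction is strictly below ``max_missing_frac``.

    The threshold is strict: a gene with exactly 20% of its entries missing is
    removed at the default 0.2.  Sample set and gene order are preserved.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    frac = matrix.mask.mean(axis=1)
    keep = frac < max_missing_frac
    if not keep.any():
        warnings.warn("filter_missing removed every gene", stacklevel=2)
    gene_ids = [g for g, k in zip(matrix.gene_ids, keep) if k]
    return ExpressionMatrix(
        gene_ids, list(matrix.sample_ids), matrix.values[keep], matrix.mask[keep]
    )


def _neighbor_distances(values: np.ndarray, mask: np.ndarray, i: int) -> np.ndarray:
    """Mean squared difference between gene ``i`` and every gene over mutually
    observed samples; NaN where fewer than one shared sample exists."""
    obs = ~mask
    shared = obs & obs[i]  # (n_genes, n_samples)
    diff = np.where(shared, values - values[i], 0.0)
    n_shared = shared.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (diff**2).sum(axis=1) / n_shared
    d[n_shared == 0] = np.nan
    return d


def impute_knn(matrix: ExpressionMatrix, k_neighbors: int = 15, seed: int = 0) -> ExpressionMatrix:
    """Fill every missing cell with the mean of its K nearest neighbour genes.

    Distance between genes is the mean squared difference over mutually
    observed samples, so genes with different overlap are comparable.  A
    neighbour is eligible for a cell only if it is itself observed at that
    sample.  Fewer than ``k_neighbors`` eligible neighbours: all of them are
    used.  None at all: the gene's own observed median is the fallback.
    Ties in distance are broken by gene id, so imputation is deterministic;
    ``seed`` is accepted for interface symmetry with the other stochastic
    steps but never consulted.

    Raises ``ValueError`` for a gene with no observed entries.
    """
    del seed
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    out = matrix.copy()
    values, mask = out.values, out.mask
    if not mask.any():
        return out
    n_obs = (~mask).sum(axis=1)
    if (n_obs == 0).any():
        bad = [g for g, n in zip(matrix.gene_ids, n_obs) if n == 0]
        raise ValueError(f"genes with no observed entries cannot be imputed: {bad[:5]}")

    gene_order = np.argsort(np.asarray(matrix.gene_ids, dtype=object))
    lex_rank = np.empty(matrix.n_genes, dtype=int)
    lex_rank[gene_order] = np.arange(matrix.n_genes)

    filled = values.copy()
    for i in np.flatnonzero(mask.any(axis=1)):
        d = _neighbor_distances(matrix.values, matrix.mask, i)
        d[i] = np.nan  # a gene is not its own neighbour
        for j in np.flatnonzero(mask[i]):
            eligible = np.flatnonzero(~matrix.mask[:, j] & ~np.isnan(d))
            if eligible.size == 0:
                filled[i, j] = float(np.median(matrix.observed(matrix.gene_ids[i])))
                continue
            order = eligible[np.lexsort((lex_rank[eligible], d[eligible]))]
            chosen = order[:k_neighbors]
            filled[i, j] = float(matrix.values[chosen, j].mean())
    out.values = filled
    out.mask = np.zeros_like(mask)
    return out


def summarize_gene(matrix: ExpressionMatrix, gene: str) -> GeneSummary:
    """Median observed log2 ratio and the over/under expression call.

    The call compares the summed magnitude of positive versus negative log2
    ratios across experiments: ``over`` when the positive mass strictly
    dominates, ``under`` otherwise (ties included) — robust to many small
    opposite-sign fluctuations.
    """
    obs = matrix.observed(gene)
    if obs.size == 0:
        raise ValueError(f"gene {gene!r} has no observed entries")
    pos = obs[obs > 0].sum()
    neg = -obs[obs < 0].sum()
    call = "over" if pos > neg else "under"
    return GeneSummary(gene, float(np.median(obs)), call)


def pairwise_correlation(matrix: ExpressionMatrix, u: str, v: str) -> float:
    """Pearson r between two genes over their mutually observed samples.

    Raises :class:`UndefinedCorrelationError` when fewer than 3 samples are
    shared or either gene has zero variance on the shared samples — callers
    must treat that case as "no evidence", never as r = 0.
    """
    iu, iv = matrix.row(u), matrix.row(v)
    shared = ~matrix.mask[iu] & ~matrix.mask[iv]
    if shared.sum() < 3:
        raise UndefinedCorrelationError(f"{u} and {v} share {int(shared.sum())} samples (< 3)")
    x = matrix.values[iu, shared]
    y = matrix.values[iv, shared]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(f"zero variance between {u} and {v}")
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def evaluate_imputation_rmse(
    matrix: ExpressionMatrix, n_deleted: int, k_neighbors: int = 15, seed: int = 0
) -> float:
    """Delete observed cells at random, re-impute, and report the RMSE.

    The matrix must be complete so deleted cells have a ground truth.
    Deterministic given ``seed``.
    """
    if matrix.mask.any():
        raise ValueError("matrix must be complete (no missing values) for RMSE evaluation")
    n_cells = matrix.values.size
    if n_deleted > n_cells:
        raise ValueError(f"cannot delete {n_deleted} of {n_cells} cells")
    if n_deleted == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_cells, size=n_deleted, replace=False)
    holed = matrix.copy()
    rows, cols = np.unravel_index(flat, matrix.values.shape)
    holed.mask[rows, cols] = True
    imputed = impute_knn(holed, k_neighbors=k_neighbors)
    err = imputed.values[rows, cols] - matrix.values[rows, cols]
    return float(np.sqrt(np.mean(err**2)))
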