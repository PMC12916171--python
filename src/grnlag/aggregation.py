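"""Neighbor-averaged smoothing of expression profiles.

Each gene's expression vector is replaced by the mean of the vectors of its
k most-similar genes (by default Pearson correlation across cells), which
damps cell-to-cell noise while preserving the shared temporal trend.  The
gene itself is excluded from its own neighbor set, otherwise k=1 would be a
no-op and defeat the purpose of smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import ExpressionMatrix

__all__ = ["AggregationConfig", "similarity_matrix", "aggregate_expression"]

_SIMILARITIES = ("pearson", "spearman", "kendall", "mutual_information")


@dataclass
class AggregationConfig:
    k: int = 10
    similarity: str = "pearson"
    include_self: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if self.similarity not in _SIMILARITIES:
            raise ValueError(f"similarity must be one of {_SIMILARITIES}")


def _pearson(values: np.ndarray) -> np.ndarray:
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    z = centered / safe[:, None]
    sim = z @ z.T
    sim[norms == 0, :] = 0.0
    sim[:, norms == 0] = 0.0
    return np.clip(sim, -1.0, 1.0)


def _rank_rows(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, values)


def _mutual_information(values: np.ndarray) -> np.ndarray:
    """Plug-in MI on an equal-width grid with ceil(sqrt(T)) bins per gene."""
    n_genes, T = values.shape
    n_bins = int(np.ceil(np.sqrt(T)))
    binned = np.empty((n_genes, T), dtype=int)
    degenerate = np.zeros(n_genes, dtype=bool)
    for i in range(n_genes):
        lo, hi = values[i].min(), values[i].max()
        if hi == lo:
            degenerate[i] = True
            binned[i] = 0
        else:
            edges = np.linspace(lo, hi, n_bins + 1)
            binned[i] = np.clip(np.digitize(values[i], edges[1:-1]), 0, n_bins - 1)
    sim = np.zeros((n_genes, n_genes))
    for i in range(n_genes):
        for j in range(i, n_genes):
            if degenerate[i] or degenerate[j]:
                continue
            joint = np.zeros((n_bins, n_bins))
            np.add.at(joint, (binned[i], binned[j]), 1.0)
            joint /= T
            pi = joint.sum(axis=1)
            pj = joint.sum(axis=0)
            nz = joint > 0
            mi = float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(pi, pj)[nz])))
            sim[i, j] = sim[j, i] = mi
    return sim


def similarity_matrix(expr: ExpressionMatrix, cfg: AggregationConfig) -> np.ndarray:
    """Symmetric gene-by-gene similarity matrix over cells.

    Zero-variance genes get similarity 0 against every other gene (their
    correlation is undefined and they carry no trend to share).
    """
    if expr.n_cells < 3:
        raise ValueError("need at least 3 cells to estimate pairwise similarity")
    values = expr.values
    if cfg.similarity == "pearson":
        return _pearson(values)
    if cfg.similarity == "spearman":
        return _pearson(_rank_rows(values))
    if cfg.similarity == "kendall":
        n = expr.n_genes
        sim = np.eye(n)
        variances = values.var(axis=1)
        for i in range(n):
            for j in range(i + 1, n):
                if variances[i] == 0 or variances[j] == 0:
                    tau = 0.0
                else:
                    tau = stats.kendalltau(values[i], values[j]).statistic
                    if not np.isfinite(tau):
                        tau = 0.0
                sim[i, j] = sim[j, i] = tau
        sim[variances == 0, :] = 0.0
        sim[:, variances == 0] = 0.0
        return sim
    return _mutual_information(values)


def aggregate_expression(expr: ExpressionMatrix, cfg: AggregationConfig) -> ExpressionMatrix:
    """Replace each gene's vector by the mean of its k most-similar genes.

    Ties at the k-th rank are broken by original gene order (stable).  With
    ``include_self`` the gene joins its own neighbor pool.
    """
    n = expr.n_genes
    max_k = n if cfg.include_self else n - 1
    if cfg.k > max_k:
        raise ValueError(f"k={cfg.k} out of range for {n} genes")
    sim = similarity_matrix(expr, cfg)
    out = np.empty_like(expr.values)
    for i in range(n):
        row = sim[i].copy()
        if not cfg.include_self:
            row[i] = -np.inf
        # stable descending sort: highest similarity first, earlier gene wins ties
        order = np.lexsort((np.arange(n), -row))
        neighbors = order[: cfg.k]
        out[i] = expr.values[neighbors].mean(axis=0)
    return ExpressionMatrix(
        gene_ids=list(expr.gene_ids),
        cell_ids=list(expr.cell_ids),
        values=out,
        pseudotime=None if expr.pseudotime is None else expr.pseudotime.copy(),
    )
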