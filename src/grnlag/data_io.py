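"""Loading, validation and preprocessing of expression data and reference networks.

The preprocessing pipeline turns a normalized gene-by-cell expression matrix
(cells ordered along a pseudotime trajectory) plus a gold-standard directed
edge list into a balanced, labelled set of TF->target candidate pairs over
highly variable genes:

1. load and validate the matrix (optionally reordering cells by pseudotime);
2. drop genes expressed in at most 10% of cells;
3. keep the ``top_n`` genes by expression variance;
4. restrict the gold standard to edges whose endpoints both survive;
5. sample an equal number of non-interacting pairs as negatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ReferenceNetwork",
    "PairSample",
    "load_expression",
    "load_network",
    "filter_low_expression",
    "select_hvg",
    "filter_gold_standard",
    "build_pair_samples",
    "split_samples",
]


@dataclass
class ExpressionMatrix:
    """A genes-by-cells real matrix with optional per-cell pseudotime.

    ``values`` has one row per entry of ``gene_ids`` and one column per entry
    of ``cell_ids``.  When ``pseudotime`` is present the columns are sorted so
    that pseudotime is nondecreasing (a stable sort, so ties keep input order).
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    pseudotime: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[bad[0]]!r}, "
                f"cell {self.cell_ids[bad[1]]!r}"
            )
        dup = pd.Index(self.gene_ids).duplicated()
        if dup.any():
            name = self.gene_ids[int(np.flatnonzero(dup)[0])]
            raise ValueError(f"duplicate gene id {name!r}")
        if self.pseudotime is not None:
            self.pseudotime = np.asarray(self.pseudotime, dtype=float)
            if self.pseudotime.shape != (len(self.cell_ids),):
                raise ValueError("pseudotime length does not match cell count")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        """New matrix keeping the boolean/index-selected genes, order preserved."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in keep],
            cell_ids=list(self.cell_ids),
            values=self.values[keep],
            pseudotime=None if self.pseudotime is None else self.pseudotime.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class ReferenceNetwork:
    """A set of directed (tf, target) edges with a category label.

    Self-loops are dropped at construction (and logged); ``lags`` optionally
    records a known time lag (in cells) per edge, used by the synthetic
    benchmark generator to expose ground truth.
    """

    edges: set[tuple[str, str]]
    label: str = "gold"
    lags: dict[tuple[str, str], int] | None = None

    def __post_init__(self) -> None:
        loops = {e for e in self.edges if e[0] == e[1]}
        if loops:
            logger.info("dropping %d self-loop(s) from %s network", len(loops), self.label)
            self.edges = set(self.edges) - loops
        else:
            self.edges = set(self.edges)

    @property
    def regulators(self) -> set[str]:
        return {tf for tf, _ in self.edges}

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class PairSample:
    """A directed TF->target candidate with a binary interaction label."""

    tf_id: str
    target_id: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def _read_dense(path: str) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed expression file {path}: {exc}") from exc
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[int(np.flatnonzero(bad.values)[0])]
            raise ValueError(
                f"non-numeric token in {path} at gene {row!r}, cell column {col!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        loc = np.argwhere(df.isna().values)[0]
        raise ValueError(
            f"missing value in {path} at gene {df.index[loc[0]]!r}, "
            f"cell {df.columns[loc[1]]!r}"
        )
    return df


def _read_mtx(path: str) -> pd.DataFrame:
    import os

    base = os.path.dirname(os.path.abspath(path))
    genes_path = os.path.join(base, "genes.txt")
    cells_path = os.path.join(base, "cells.txt")
    for side in (genes_path, cells_path):
        if not os.path.exists(side):
            raise FileNotFoundError(f"MTX sidecar file missing: {side}")
    raw = mmread(path)
    mat = np.asarray(raw.todense()) if hasattr(raw, "todense") else np.asarray(raw)
    genes = [ln.strip() for ln in open(genes_path) if ln.strip()]
    cells = [ln.strip() for ln in open(cells_path) if ln.strip()]
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"MTX shape {mat.shape} does not match sidecars "
            f"({len(genes)} genes, {len(cells)} cells)"
        )
    return pd.DataFrame(mat, index=genes, columns=cells)


def load_expression(path: str, pseudotime_path: str | None = None) -> ExpressionMatrix:
    """Load a genes-by-cells matrix from dense TSV/CSV or MatrixMarket MTX.

    Dense files carry gene ids in the first column and a header row of cell
    ids.  MTX files expect ``genes.txt`` / ``cells.txt`` sidecars in the same
    directory.  When ``pseudotime_path`` (two-column TSV: cell id, pseudotime)
    is given, cells are stably reordered by nondecreasing pseudotime.
    """
    if str(path).endswith(".mtx"):
        df = _read_mtx(path)
    else:
        df = _read_dense(path)

    pt = None
    if pseudotime_path is not None:
        pt_df = pd.read_csv(pseudotime_path, sep="\t", header=None, comment="#")
        if pt_df.shape[1] < 2:
            raise ValueError(f"pseudotime file {pseudotime_path} needs >=2 columns")
        # tolerate an optional header line
        try:
            float(pt_df.iloc[0, 1])
        except (TypeError, ValueError):
            pt_df = pt_df.iloc[1:]
        mapping = dict(zip(pt_df.iloc[:, 0].astype(str), pt_df.iloc[:, 1].astype(float)))
        missing = [c for c in df.columns if str(c) not in mapping]
        if missing:
            raise ValueError(
                f"pseudotime missing for {len(missing)} cell(s), e.g. {missing[0]!r}"
            )
        pt = np.array([mapping[str(c)] for c in df.columns])
        order = np.argsort(pt, kind="stable")
        df = df.iloc[:, order]
        pt = pt[order]

    expr = ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        cell_ids=[str(c) for c in df.columns],
        values=df.values.astype(float),
        pseudotime=pt,
    )
    zero_frac = float((expr.values == 0).mean())
    logger.info(
        "loaded %d genes x %d cells from %s (zero fraction %.3f)",
        expr.n_genes, expr.n_cells, path, zero_frac,
    )
    return expr


def load_network(path: str, label: str = "gold") -> ReferenceNetwork:
    """Load a directed edge list from a TSV with >=2 columns (tf, target)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"network file {path} needs >=2 columns (tf, target)")
    # tolerate a header row of non-data labels such as "tf\ttarget"
    if df.iloc[0, 0].lower() in {"tf", "regulator", "source"}:
        df = df.iloc[1:]
    edges = {(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])}
    return ReferenceNetwork(edges=edges, label=label)


def filter_low_expression(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes expressed (value > 0) in at most floor(T/10) cells.

    The boundary gene — nonzero in exactly floor(T/10) cells — is removed.
    """
    if expr.n_cells < 10:
        raise ValueError("need at least 10 cells to apply the 10% expression filter")
    threshold = expr.n_cells // 10
    nonzero = (expr.values > 0).sum(axis=1)
    keep = nonzero > threshold
    if not keep.any():
        raise ValueError(
            "all genes fall at or below the 10% expression threshold; "
            "review the threshold or the input normalization"
        )
    logger.info("low-expression filter removed %d of %d genes", int((~keep).sum()), expr.n_genes)
    return expr.subset_genes(keep)


def select_hvg(expr: ExpressionMatrix, top_n: int, log1p: bool = False) -> ExpressionMatrix:
    """Keep the ``top_n`` genes by per-gene expression variance across cells.

    Ties at the cutoff are broken by original gene order (stable).  ``log1p``
    computes the variance ranking on log1p-transformed values while returning
    the untransformed matrix.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    if top_n > expr.n_genes:
        raise ValueError(f"top_n={top_n} exceeds available genes ({expr.n_genes})")
    vals = np.log1p(expr.values) if log1p else expr.values
    variances = vals.var(axis=1)
    # stable: sort by (-variance, original index)
    order = np.lexsort((np.arange(expr.n_genes), -variances))
    keep = np.sort(order[:top_n])
    return expr.subset_genes(keep)


def filter_gold_standard(net: ReferenceNetwork, expr: ExpressionMatrix) -> ReferenceNetwork:
    """Keep edges whose TF and target both appear in the expression matrix."""
    genes = set(expr.gene_ids)
    kept = {e for e in net.edges if e[0] in genes and e[1] in genes}
    logger.info("gold-standard filter kept %d of %d edges", len(kept), len(net.edges))
    if not kept:
        raise ValueError("no gold-standard edge survives the gene filter; nothing to learn from")
    lags = None
    if net.lags is not None:
        lags = {e: lag for e, lag in net.lags.items() if e in kept}
    return ReferenceNetwork(edges=kept, label=net.label, lags=lags)


def build_pair_samples(
    gold: ReferenceNetwork, expr: ExpressionMatrix, seed: int
) -> list[PairSample]:
    """All gold edges as positives plus an equal-size seeded random negative set.

    Negatives are drawn uniformly without replacement from {(tf, g)} where tf
    is a regulator in the gold standard, g is any other gene in the matrix,
    and (tf, g) is not a gold edge.
    """
    genes = set(expr.gene_ids)
    for tf, tg in gold.edges:
        if tf not in genes or tg not in genes:
            raise ValueError(f"gold edge ({tf}, {tg}) references a gene absent from the matrix")
    positives = [PairSample(tf, tg, 1) for tf, tg in sorted(gold.edges)]
    tfs = sorted(gold.regulators)
    pool = [
        (tf, g)
        for tf in tfs
        for g in expr.gene_ids
        if g != tf and (tf, g) not in gold.edges
    ]
    if len(pool) < len(positives):
        raise ValueError(
            f"negative candidate pool ({len(pool)}) smaller than positive count "
            f"({len(positives)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=len(positives), replace=False)
    negatives = [PairSample(pool[i][0], pool[i][1], 0) for i in sorted(idx)]
    return positives + negatives


def split_samples(
    samples: list[PairSample], seed: int, fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
) -> tuple[list[PairSample], list[PairSample], list[PairSample]]:
    """Stratified train/validation/test split in a 3:1:1 ratio.

    Within each class the assignment is a seeded shuffle; remainders after the
    floor division go to the training set.  The three subsets are disjoint and
    exhaustive, and class proportions match the input up to rounding.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[PairSample]] = {0: [], 1: []}
    for s in samples:
        by_class[s.label].append(s)
    for label, members in by_class.items():
        if len(members) < 5:
            raise ValueError(
                f"class {label} has only {len(members)} samples; need >=5 to stratify 3:1:1"
            )
    train: list[PairSample] = []
    val: list[PairSample] = []
    test: list[PairSample] = []
    for label in (1, 0):
        members = list(by_class[label])
        perm = rng.permutation(len(members))
        members = [members[i] for i in perm]
        n = len(members)
        n_val = int(n * fractions[1])
        n_test = int(n * fractions[2])
        n_train = n - n_val - n_test  # remainder goes to train
        train += members[:n_train]
        val += members[n_train : n_train + n_val]
        test += members[n_train + n_val :]
    return train, val, test
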