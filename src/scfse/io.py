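"""Reading, writing and preprocessing of cells × genes count matrices.

The preprocessing chain mirrors the standard scRNA-seq recipe: drop genes
with zero total count, scale every cell to a common library size, apply a
``log2(x + 1)`` transform, and keep the top-``D`` highly variable genes
(HVGs) ranked by binned dispersion.  The HVG matrix is the search space for
the downstream feature-selection step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "read_count_matrix",
    "write_count_matrix",
    "filter_zero_genes",
    "normalize_log",
    "select_hvg",
]


class MatrixFormatError(ValueError):
    """Raised when an input matrix file is malformed or fails validation."""


def _check_unique(ids: list[str], axis: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise MatrixFormatError(f"duplicate {axis} identifier: {dup!r}")


@dataclass
class CountMatrix:
    """Raw nonnegative integer counts, cells in rows, genes in columns."""

    values: np.ndarray
    cell_ids: list[str] = field(repr=False)
    gene_ids: list[str] = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise MatrixFormatError("count matrix must be two-dimensional")
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise MatrixFormatError(
                f"identifier counts ({len(self.cell_ids)} cells, "
                f"{len(self.gene_ids)} genes) do not match matrix shape "
                f"{self.values.shape}"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        if not np.issubdtype(self.values.dtype, np.integer):
            as_float = self.values.astype(float)
            if not np.all(np.isfinite(as_float)) or np.any(as_float != np.round(as_float)):
                bad = np.argwhere(as_float != np.round(as_float))
                loc = tuple(bad[0]) if len(bad) else "?"
                raise MatrixFormatError(f"non-integer count at position {loc}")
            self.values = as_float.astype(np.int64)
        if np.any(self.values < 0):
            r, c = np.argwhere(self.values < 0)[0]
            raise MatrixFormatError(
                f"negative count {self.values[r, c]} at cell "
                f"{self.cell_ids[r]!r}, gene {self.gene_ids[c]!r}"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class ExpressionMatrix:
    """Normalized, log2-transformed expression; rows cells, columns genes."""

    values: np.ndarray
    cell_ids: list[str] = field(repr=False)
    gene_ids: list[str] = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


def _read_names(path: Path) -> list[str]:
    with open(path) as fh:
        names = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return names


def read_count_matrix(
    path: str | Path,
    format: str = "csv",
    mtx_orientation: str = "genes-cells",
) -> CountMatrix:
    """Read a count matrix from CSV, TSV or MatrixMarket MTX.

    CSV/TSV layout: header row of gene identifiers, first column cell
    identifiers.  MTX input expects ``genes.tsv`` and ``barcodes.tsv``
    companions next to the matrix file; ``mtx_orientation`` declares whether
    the stored matrix is ``genes-cells`` (10x convention, transposed on
    load) or ``cells-genes``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        _check_unique(header, "gene")  # pandas would silently mangle duplicates
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise MatrixFormatError(f"could not parse {path}: {exc}") from exc
        return CountMatrix(df.to_numpy(), list(df.index), header)
    if format == "mtx":
        genes_path = path.parent / "genes.tsv"
        cells_path = path.parent / "barcodes.tsv"
        for p in (genes_path, cells_path):
            if not p.exists():
                raise FileNotFoundError(f"MTX companion file missing: {p}")
        mat = mmread(path)
        dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        if mtx_orientation == "genes-cells":
            dense = dense.T
        elif mtx_orientation != "cells-genes":
            raise ValueError(f"unknown mtx orientation {mtx_orientation!r}")
        return CountMatrix(dense, _read_names(cells_path), _read_names(genes_path))
    raise ValueError(f"unknown format {format!r}")


def write_count_matrix(
    m: CountMatrix,
    path: str | Path,
    format: str = "csv",
    mtx_orientation: str = "genes-cells",
) -> None:
    """Write a count matrix in the same dialects :func:`read_count_matrix` reads."""
    path = Path(path)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.DataFrame(m.values, index=m.cell_ids, columns=m.gene_ids)
        df.to_csv(path, sep=sep)
        return
    if format == "mtx":
        stored = m.values.T if mtx_orientation == "genes-cells" else m.values
        mmwrite(str(path), sparse.coo_matrix(stored))
        with open(path.parent / "genes.tsv", "w") as fh:
            fh.write("".join(f"{g}\n" for g in m.gene_ids))
        with open(path.parent / "barcodes.tsv", "w") as fh:
            fh.write("".join(f"{c}\n" for c in m.cell_ids))
        return
    raise ValueError(f"unknown format {format!r}")


def filter_zero_genes(m: CountMatrix) -> CountMatrix:
    """Drop genes with zero total count across all cells, preserving order."""
    keep = m.values.sum(axis=0) > 0
    if not keep.any():
        raise ValueError("all genes have zero counts; empty feature space")
    return CountMatrix(
        m.values[:, keep],
        m.cell_ids,
        [g for g, k in zip(m.gene_ids, keep) if k],
    )


def scale_to_library_size(m: CountMatrix, scale: float | None = None) -> np.ndarray:
    """Per-cell linear scaling of counts to a common library size.

    Returns the linear (pre-log) matrix; ``scale`` defaults to the median
    per-cell total.  This intermediate is exactly invariant to multiplying
    all counts by a common positive factor.
    """
    totals = m.values.sum(axis=1).astype(float)
    zero = totals == 0
    if zero.any():
        bad = [m.cell_ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"cells with zero total count: {bad}")
    if scale is None:
        scale = float(np.median(totals))
    if scale <= 0:
        raise ValueError("scale must be positive")
    return m.values * (scale / totals)[:, None]


def normalize_log(m: CountMatrix, scale: float | None = None) -> ExpressionMatrix:
    """Library-size normalization followed by ``log2(x + 1)``.

    Each cell's counts are scaled so its total equals ``scale`` (default:
    median per-cell total), then log2-transformed.  A zero count maps to 0.
    """
    linear = scale_to_library_size(m, scale)
    return ExpressionMatrix(np.log2(linear + 1.0), m.cell_ids, m.gene_ids)


def dispersion_ranking(expr: ExpressionMatrix, n_bins: int = 20) -> np.ndarray:
    """Variability score per gene: binned, z-scored dispersion of log-expression.

    Dispersion is variance/mean per gene; genes are binned by mean expression
    into ``n_bins`` equal-width bins and the dispersion is z-scored within
    each bin so lowly and highly expressed genes compete fairly.
    Zero-variance genes score ``-inf`` (never variable).
    """
    x = expr.values
    mean = x.mean(axis=0)
    var = x.var(axis=0)
    disp = np.divide(var, mean, out=np.zeros_like(var), where=mean > 0)
    bins = pd.cut(mean, bins=n_bins, labels=False, duplicates="drop")
    bins = np.asarray(bins, dtype=float)
    bins[np.isnan(bins)] = 0
    score = np.empty_like(disp)
    for b in np.unique(bins):
        idx = bins == b
        mu, sd = disp[idx].mean(), disp[idx].std()
        score[idx] = (disp[idx] - mu) / sd if sd > 0 else 0.0
    constant = np.ptp(x, axis=0) == 0  # exact, unlike var == 0 in floats
    score[constant] = -np.inf
    return score


def select_hvg(expr: ExpressionMatrix, D: int = 2000) -> ExpressionMatrix:
    """Keep the top-``D`` highly variable genes, preserving input gene order.

    If the matrix already has at most ``D`` genes it is returned unchanged.
    """
    if D < 2:
        raise ValueError("D must be at least 2")
    if expr.n_genes <= D:
        return expr
    score = dispersion_ranking(expr)
    # descending score, ties by original index for determinism
    order = np.lexsort((np.arange(expr.n_genes), -score))
    keep = np.zeros(expr.n_genes, dtype=bool)
    keep[order[:D]] = True
    return ExpressionMatrix(
        expr.values[:, keep],
        expr.cell_ids,
        [g for g, k in zip(expr.gene_ids, keep) if k],
    )
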