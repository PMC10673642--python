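"""Count-matrix I/O and the normalization stack.

The method operates on three derived matrices: ``Y^C`` (each cell scaled to a
common total, the topic model's input), ``Y^G`` (each gene divided by its mean
count across cells) and ``Y = log10(Y^G + 1.01)`` (the dropout mixture's
input).  The pseudo-count 1.01 maps observed zeros to log10(1.01) > 0 so every
transformed entry lies in the Gamma support.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PSEUDO_COUNT = 1.01


class ValidationError(ValueError):
    """Raised when an input matrix violates the count-matrix contract."""


@dataclass
class CountMatrix:
    """Raw cells x genes non-negative counts with row/column identifiers."""

    values: np.ndarray  # (I, J) float array, non-negative
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        validate_counts(self.values, self.cell_ids, self.gene_ids)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.values.copy(), list(self.cell_ids), list(self.gene_ids))


@dataclass
class NormalizedData:
    """The (Y^C, Y^G, Y) triple derived from a CountMatrix.

    ``y_lib_log`` additionally carries log10 of library-size-normalized counts
    (each cell scaled to the median library), the scale on which the dropout
    mixture is fit by default: unlike the per-gene matrix it preserves
    absolute expression differences between genes, which is what separates
    "zero in a strongly expressed gene" (suspicious) from "zero in a barely
    expressed gene" (expected).
    """

    y_cell: np.ndarray
    y_gene: np.ndarray
    y_log: np.ndarray
    y_lib_log: np.ndarray = None
    library_sizes: np.ndarray = None  # per-cell total counts of the source matrix
    pseudo_count: float = PSEUDO_COUNT
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)


def validate_counts(values: np.ndarray, cell_ids, gene_ids) -> None:
    if values.ndim != 2:
        raise ValidationError(f"expected a 2-D matrix, got ndim={values.ndim}")
    n_cells, n_genes = values.shape
    if len(cell_ids) != n_cells:
        raise ValidationError(f"{len(cell_ids)} cell ids for {n_cells} rows")
    if len(gene_ids) != n_genes:
        raise ValidationError(f"{len(gene_ids)} gene ids for {n_genes} columns")
    if len(set(cell_ids)) != n_cells:
        raise ValidationError("duplicate cell ids")
    if len(set(gene_ids)) != n_genes:
        raise ValidationError("duplicate gene ids")
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(f"non-finite entry at cell {i}, gene {j}")
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative entry {values[i, j]} at cell {i} ({cell_ids[i]}), "
            f"gene {j} ({gene_ids[j]})"
        )


def _detect_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in {".csv", ".tsv", ".txt"}:
        return "csv"
    if ext == ".mtx":
        return "mtx"
    if ext == ".h5ad":
        return "h5ad"
    raise ValueError(f"cannot detect format from extension {ext!r}")


def read_counts(path: str, format: str = "auto") -> CountMatrix:
    """Read a cells x genes count matrix from CSV/TSV, MTX or h5ad.

    MTX sidecars ``genes.tsv``/``features.tsv`` and ``barcodes.tsv`` are looked
    up next to the .mtx file; the CellRanger genes-as-rows dialect is
    transposed so cells are rows in memory.
    """
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    fmt = _detect_format(path) if format == "auto" else format
    if fmt == "csv":
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, index_col=0, sep=sep)
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
            raise ValidationError(f"non-numeric entries in columns {list(bad)}")
        return CountMatrix(vals, list(df.index), list(df.columns))
    if fmt == "mtx":
        from scipy.io import mmread

        mat = np.asarray(mmread(path).todense(), dtype=float)
        d = os.path.dirname(path)
        genes = _read_sidecar(d, ("genes.tsv", "features.tsv"))
        cells = _read_sidecar(d, ("barcodes.tsv", "cells.tsv"))
        if mat.shape == (len(genes), len(cells)):
            logger.info("MTX stored genes x cells; transposing to cells x genes")
            mat = mat.T
        elif mat.shape != (len(cells), len(genes)):
            raise ValidationError(
                f"MTX shape {mat.shape} matches neither orientation of "
                f"{len(cells)} barcodes x {len(genes)} genes"
            )
        return CountMatrix(mat, cells, genes)
    if fmt == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        x = adata.X
        if hasattr(x, "toarray"):
            x = x.toarray()
        return CountMatrix(np.asarray(x, dtype=float), list(adata.obs_names), list(adata.var_names))
    raise ValueError(f"unknown format {fmt!r}")


def _read_sidecar(directory: str, names: tuple[str, ...]) -> list[str]:
    for name in names:
        p = os.path.join(directory, name)
        if os.path.exists(p):
            with open(p) as fh:
                return [line.split("\t")[0].strip() for line in fh if line.strip()]
    raise IOError(f"missing sidecar (tried {names}) in {directory}")


def write_counts(matrix: CountMatrix, path: str, format: str = "auto") -> None:
    """Write a CountMatrix; read_counts(write_counts(m)) round-trips exactly."""
    fmt = _detect_format(path) if format == "auto" else format
    parent = os.path.dirname(path)
    if parent and not os.path.isdir(parent):
        raise IOError(f"directory does not exist: {parent}")
    if fmt == "csv":
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        pd.DataFrame(matrix.values, index=matrix.cell_ids, columns=matrix.gene_ids).to_csv(
            path, sep=sep
        )
    elif fmt == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        # genes x cells on disk, matching the common CellRanger layout
        mmwrite(path, csr_matrix(matrix.values.T))
        d = os.path.dirname(path) or "."
        with open(os.path.join(d, "genes.tsv"), "w") as fh:
            fh.write("\n".join(matrix.gene_ids) + "\n")
        with open(os.path.join(d, "barcodes.tsv"), "w") as fh:
            fh.write("\n".join(matrix.cell_ids) + "\n")
    elif fmt == "h5ad":
        import anndata as ad

        adata = ad.AnnData(
            X=matrix.values.copy(),
            obs=pd.DataFrame(index=matrix.cell_ids),
            var=pd.DataFrame(index=matrix.gene_ids),
        )
        adata.write_h5ad(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def filter_qc(
    matrix: CountMatrix, min_counts_per_cell: int = 1, min_cells_per_gene: int = 1
) -> CountMatrix:
    """Drop shallow cells, then genes detected in too few cells.

    Cells with total count < ``min_counts_per_cell`` are removed first, then
    genes with a positive count in fewer than ``min_cells_per_gene`` of the
    surviving cells.  Survivor order is preserved.
    """
    if min_counts_per_cell < 0 or min_cells_per_gene < 0:
        raise ValueError("QC thresholds must be >= 0")
    x = matrix.values
    keep_cells = x.sum(axis=1) >= min_counts_per_cell
    x2 = x[keep_cells]
    keep_genes = (x2 > 0).sum(axis=0) >= min_cells_per_gene
    n_cells_dropped = int((~keep_cells).sum())
    n_genes_dropped = int((~keep_genes).sum())
    if n_cells_dropped or n_genes_dropped:
        logger.info("QC removed %d cells and %d genes", n_cells_dropped, n_genes_dropped)
    if keep_cells.sum() == 0 or keep_genes.sum() == 0:
        raise ValidationError(
            "QC removed everything; relax min_counts_per_cell/min_cells_per_gene"
        )
    return CountMatrix(
        x2[:, keep_genes],
        [c for c, k in zip(matrix.cell_ids, keep_cells) if k],
        [g for g, k in zip(matrix.gene_ids, keep_genes) if k],
    )


def normalize(matrix: CountMatrix, cell_target: float = 1.0) -> NormalizedData:
    """Produce Y^C (cell-normalized), Y^G (gene-normalized) and Y = log10(Y^G + 1.01).

    Y^C row i is X_i scaled so the row sums to ``cell_target`` (relative
    abundance when 1.0); Y^G column j is X_.j divided by the gene's mean count
    across cells.  All-zero rows/columns are left at zero with a warning; an
    observed zero maps to y_log = log10(1.01).
    """
    if cell_target <= 0:
        raise ValueError("cell_target must be positive")
    x = matrix.values
    row_sums = x.sum(axis=1, keepdims=True)
    zero_rows = row_sums[:, 0] == 0
    if zero_rows.any():
        logger.warning("%d all-zero cells left unnormalized", int(zero_rows.sum()))
    safe_rows = np.where(row_sums > 0, row_sums, 1.0)
    y_cell = x * cell_target / safe_rows

    col_means = x.mean(axis=0, keepdims=True)
    zero_cols = col_means[0] == 0
    if zero_cols.any():
        logger.warning("%d all-zero genes left unnormalized", int(zero_cols.sum()))
    safe_cols = np.where(col_means > 0, col_means, 1.0)
    y_gene = x / safe_cols

    y_log = np.log10(y_gene + PSEUDO_COUNT)

    libs = row_sums[row_sums[:, 0] > 0, 0]
    median_lib = float(np.median(libs)) if libs.size else 1.0
    y_lib_log = np.log10(x * median_lib / safe_rows + PSEUDO_COUNT)
    return NormalizedData(
        y_cell=y_cell,
        y_gene=y_gene,
        y_log=y_log,
        y_lib_log=y_lib_log,
        library_sizes=row_sums[:, 0].copy(),
        cell_ids=list(matrix.cell_ids),
        gene_ids=list(matrix.gene_ids),
    )
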