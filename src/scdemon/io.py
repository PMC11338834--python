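"""Expression-matrix I/O, normalization, gene sparsity, and gene filtering.

The pipeline operates on a cells x genes matrix ``X`` with ``n`` cells (rows)
and ``g`` genes (columns), held sparse throughout.  Cell metadata carries at
minimum a ``batch_id`` column, which defines the resampling unit for the
batch bootstrap used to stabilize edge estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("scdemon")

__all__ = [
    "ExpressionMatrix",
    "GeneSparsity",
    "read_matrix",
    "write_matrix",
    "normalize",
    "compute_sparsity",
    "filter_genes",
]


class FormatError(ValueError):
    """Input files are malformed or mutually inconsistent."""


@dataclass
class ExpressionMatrix:
    """Validated cells x genes expression matrix with cell metadata.

    Parameters
    ----------
    values
        Non-negative sparse matrix, cells in rows and genes in columns.
    gene_ids, cell_ids
        Unique identifiers for columns and rows respectively.
    cell_meta
        Table indexed by cell id; must contain a non-missing ``batch_id``
        column (the bootstrap resampling unit, typically one sample).
    normalized
        False for raw counts, True after library-size normalization.
    """

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame
    normalized: bool = False

    def __post_init__(self):
        self.values = sp.csr_matrix(self.values, dtype=np.float64)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n, g = self.values.shape
        if n < 2 or g < 2:
            raise ValueError(f"need at least 2 cells and 2 genes, got {n} x {g}")
        if len(self.gene_ids) != g:
            raise FormatError(f"{len(self.gene_ids)} gene ids for {g} matrix columns")
        if len(self.cell_ids) != n:
            raise FormatError(f"{len(self.cell_ids)} cell ids for {n} matrix rows")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids")
        missing = set(self.cell_ids) - set(self.cell_meta.index)
        if missing:
            raise FormatError(
                f"{len(missing)} cells absent from metadata (e.g. {sorted(missing)[:3]})"
            )
        if "batch_id" not in self.cell_meta.columns:
            raise FormatError("cell metadata must contain a 'batch_id' column")
        self.cell_meta = self.cell_meta.loc[list(self.cell_ids)]
        if self.cell_meta["batch_id"].isna().any():
            raise ValueError("batch_id contains missing values")
        data = self.values.data
        if data.size and (not np.all(np.isfinite(data)) or data.min() < 0):
            raise ValueError("expression values must be finite and non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def batches(self) -> np.ndarray:
        """Sorted unique batch labels."""
        return np.array(sorted(self.cell_meta["batch_id"].astype(str).unique()))

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ExpressionMatrix(
            values=self.values[idx],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[idx],
            cell_meta=self.cell_meta.iloc[idx],
            normalized=self.normalized,
        )

    def subset_genes(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return ExpressionMatrix(
            values=self.values[:, idx],
            gene_ids=self.gene_ids[idx],
            cell_ids=self.cell_ids,
            cell_meta=self.cell_meta,
            normalized=self.normalized,
        )

    def to_anndata(self):
        """Convert to :class:`anndata.AnnData` (optional dependency)."""
        import anndata

        return anndata.AnnData(
            X=self.values.copy(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )


@dataclass
class GeneSparsity:
    """Per-gene expressed fraction (sparsity) and its log10."""

    fraction_expressed: np.ndarray
    log10_sparsity: np.ndarray = field(default=None)

    def __post_init__(self):
        self.fraction_expressed = np.asarray(self.fraction_expressed, dtype=float)
        if self.log10_sparsity is None:
            with np.errstate(divide="ignore"):
                self.log10_sparsity = np.log10(self.fraction_expressed)


def _read_id_file(path: Path) -> np.ndarray:
    """First column of a headerless TSV (features.tsv / barcodes.tsv style)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].to_numpy(dtype=object)


def read_matrix(
    path: str | Path,
    format: str = "mtx",
    meta_path: str | Path | None = None,
    features_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix plus cell metadata.

    ``format="mtx"``: MatrixMarket coordinate file with companion
    ``features.tsv`` and ``barcodes.tsv`` (defaults: same directory).  The
    matrix may store genes in rows or columns; the orientation is
    auto-detected from the companion file lengths.

    ``format="dense_tsv"``: delimited text, header row = gene ids, first
    column = cell ids.

    ``meta_path``: TSV with header, first column = cell id, containing at
    least ``batch_id``.  Cells without metadata rows are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx":
        mat = scipy.io.mmread(path)
        features_path = Path(features_path) if features_path else path.parent / "features.tsv"
        barcodes_path = Path(barcodes_path) if barcodes_path else path.parent / "barcodes.tsv"
        genes = _read_id_file(features_path)
        cells = _read_id_file(barcodes_path)
        r, c = mat.shape
        if r == len(cells) and c == len(genes):
            pass  # cells x genes
        elif r == len(genes) and c == len(cells):
            mat = mat.T  # CellRanger-style genes x cells
        else:
            raise FormatError(
                f"matrix shape {mat.shape} matches neither {len(cells)} barcodes x "
                f"{len(genes)} features nor its transpose"
            )
        values = sp.csr_matrix(mat)
    elif format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        genes = df.columns.to_numpy(dtype=object)
        cells = df.index.to_numpy(dtype=object).astype(object)
        cells = np.array([str(c) for c in cells], dtype=object)
        values = sp.csr_matrix(df.to_numpy(dtype=np.float64))
    else:
        raise ValueError(f"unknown format {format!r}; use 'mtx' or 'dense_tsv'")

    if meta_path is None:
        raise ValueError("meta_path is required (needs at least a batch_id column)")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype={0: str})
    meta.index = meta.index.astype(str)
    return ExpressionMatrix(values=values, gene_ids=genes, cell_ids=cells, cell_meta=meta)


def write_matrix(X: ExpressionMatrix, out_dir: str | Path, format: str = "mtx") -> None:
    """Write matrix + ids + metadata; inverse of :func:`read_matrix`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if format == "mtx":
        scipy.io.mmwrite(out / "matrix.mtx", sp.coo_matrix(X.values))
        pd.Series(X.gene_ids).to_csv(out / "features.tsv", sep="\t", header=False, index=False)
        pd.Series(X.cell_ids).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)
    elif format == "dense_tsv":
        df = pd.DataFrame(X.values.toarray(), index=X.cell_ids, columns=X.gene_ids)
        df.to_csv(out / "matrix.tsv", sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")
    X.cell_meta.to_csv(out / "meta.tsv", sep="\t", index_label="cell_id")


def normalize(
    X: ExpressionMatrix, target_sum: float = 10_000.0, force: bool = False
) -> ExpressionMatrix:
    """Library-size normalize to ``target_sum`` counts per cell, then log1p.

    Zero-count cells cannot be normalized and are dropped with a warning.
    """
    if X.normalized and not force:
        raise ValueError("matrix already normalized (pass force=True to renormalize)")
    totals = np.asarray(X.values.sum(axis=1)).ravel()
    keep = totals > 0
    if not keep.all():
        n_drop = int((~keep).sum())
        warnings.warn(f"dropping {n_drop} zero-count cells before normalization")
        logger.warning("dropping %d zero-count cells", n_drop)
        X = X.subset_cells(keep)
        totals = totals[keep]
    vals = X.values.copy().astype(np.float64)
    scale = target_sum / totals
    vals = sp.diags(scale) @ vals
    vals.data = np.log1p(vals.data)
    return replace(X, values=sp.csr_matrix(vals), normalized=True)


def compute_sparsity(X: ExpressionMatrix) -> GeneSparsity:
    """Fraction of cells expressing each gene, with log10 transform.

    Genes with fraction 0 carry ``log10_sparsity = -inf`` and must be
    filtered before the sparsity calibration step.
    """
    nnz = X.values.getnnz(axis=0).astype(float)
    return GeneSparsity(fraction_expressed=nnz / X.n_cells)


def filter_genes(
    X: ExpressionMatrix, sp_: GeneSparsity, min_fraction: float = 0.05
) -> ExpressionMatrix:
    """Keep genes expressed in strictly more than ``min_fraction`` of cells."""
    if len(sp_.fraction_expressed) != X.n_genes:
        raise ValueError("sparsity vector length does not match gene count")
    keep = sp_.fraction_expressed > min_fraction
    if not keep.any():
        raise ValueError(
            f"no genes expressed in more than {min_fraction:.0%} of cells; "
            "lower min_fraction or check that the matrix is cells x genes"
        )
    return X.subset_genes(keep)
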