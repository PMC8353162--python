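"""Count-matrix containers, 10x-style triplet / dense TSV I/O, droplet QC.

Matrices are stored genes x cells as sparse integer counts.  The Matrix
Market triplet layout mirrors the 10x convention: ``matrix.mtx`` +
headerless ``features.tsv`` (gene_id, gene_name) + ``barcodes.tsv``, with
per-cell metadata in ``cells.tsv``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class CountMatrixError(ValueError):
    """Malformed count matrix or inconsistent triplet files."""


class EmptyResultError(ValueError):
    """A filter removed every cell."""


@dataclass
class CountMatrix:
    """Sparse genes x cells raw UMI counts with identifiers and metadata."""

    counts: sp.csr_matrix
    genes: pd.Index
    cells: pd.Index
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.genes = pd.Index(self.genes, name="gene")
        self.cells = pd.Index(self.cells, name="barcode")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.cells)
        self.validate()

    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.genes) != n_genes or len(self.cells) != n_cells:
            raise CountMatrixError(
                f"identifier/matrix dimension mismatch: matrix {self.counts.shape}, "
                f"{len(self.genes)} genes, {len(self.cells)} barcodes"
            )
        if self.genes.duplicated().any():
            raise CountMatrixError("duplicate gene identifiers")
        if self.cells.duplicated().any():
            raise CountMatrixError("duplicate cell barcodes")
        data = self.counts.data
        if data.size:
            if not np.issubdtype(data.dtype, np.integer):
                if not np.allclose(data, np.round(data)):
                    raise CountMatrixError("counts must be integral")
                self.counts = self.counts.astype(np.int64)
            if self.counts.data.size and self.counts.data.min() < 0:
                raise CountMatrixError("counts must be non-negative")
        if not self.cell_meta.index.equals(self.cells):
            missing = self.cells.difference(self.cell_meta.index)
            if len(missing):
                raise CountMatrixError(f"cell_meta missing barcodes, e.g. {missing[:3].tolist()}")
            self.cell_meta = self.cell_meta.loc[self.cells]

    # -- basic views ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts.toarray(), index=self.genes, columns=self.cells)

    def subset_cells(self, barcodes) -> "CountMatrix":
        idx = self.cells.get_indexer(pd.Index(barcodes))
        if (idx < 0).any():
            raise KeyError("unknown barcodes in subset_cells")
        return CountMatrix(
            counts=self.counts[:, idx],
            genes=self.genes,
            cells=self.cells[idx],
            cell_meta=self.cell_meta.iloc[idx].copy(),
        )

    def subset_genes(self, genes) -> "CountMatrix":
        idx = self.genes.get_indexer(pd.Index(genes))
        if (idx < 0).any():
            raise KeyError("unknown genes in subset_genes")
        return CountMatrix(
            counts=self.counts[idx],
            genes=self.genes[idx],
            cells=self.cells,
            cell_meta=self.cell_meta.copy(),
        )

    def gene_vector(self, gene: str) -> np.ndarray:
        i = self.genes.get_loc(gene)
        return np.asarray(self.counts[i].todense()).ravel()


@dataclass
class QCThresholds:
    """Per-replicate droplet filters.

    The shipped defaults (min_genes=500, max_genes=9000, max_mito_frac=0.1,
    UMI bounds unset) are package conventions, not published per-replicate
    values — tune them per dataset.
    """

    min_genes: int = 500
    max_genes: int | None = 9000
    min_umis: int | None = None
    max_umis: int | None = None
    max_mito_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.max_genes is not None and self.min_genes > self.max_genes:
            raise ValueError("min_genes > max_genes")
        if (
            self.min_umis is not None
            and self.max_umis is not None
            and self.min_umis > self.max_umis
        ):
            raise ValueError("min_umis > max_umis")
        if not 0 <= self.max_mito_frac <= 1:
            raise ValueError("max_mito_frac must lie in [0, 1]")


def read_counts(path: str | Path, format: str = "mtx_triplet") -> CountMatrix:
    """Read a count matrix from a 10x-style triplet directory or dense TSV."""
    path = Path(path)
    if format == "mtx_triplet":
        return _read_mtx_triplet(path)
    if format == "dense_tsv":
        return _read_dense_tsv(path)
    raise ValueError(f"unknown format {format!r}; use 'mtx_triplet' or 'dense_tsv'")


def write_counts(cm: CountMatrix, path: str | Path, format: str = "mtx_triplet") -> None:
    """Write a count matrix; inverse of :func:`read_counts`."""
    path = Path(path)
    if format == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(
            str(path / "matrix.mtx"), sp.coo_matrix(cm.counts), field="integer"
        )
        pd.DataFrame({"gene_id": cm.genes, "gene_name": cm.genes}).to_csv(
            path / "features.tsv", sep="\t", header=False, index=False
        )
        pd.Series(cm.cells).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
        meta = cm.cell_meta.copy()
        meta.index.name = "barcode"
        meta.to_csv(path / "cells.tsv", sep="\t")
    elif format == "dense_tsv":
        cm.to_frame().to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_mtx_triplet(path: Path) -> CountMatrix:
    mtx_path = path / "matrix.mtx"
    for p in (mtx_path, path / "features.tsv", path / "barcodes.tsv"):
        if not p.exists():
            raise FileNotFoundError(p)
    mat = scipy.io.mmread(str(mtx_path))
    if not np.issubdtype(mat.dtype, np.integer):
        if not np.allclose(mat.data, np.round(mat.data)):
            raise CountMatrixError("matrix.mtx contains non-integer entries")
        mat = mat.astype(np.int64)
    features = pd.read_csv(path / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0]
    if len(features) != mat.shape[0]:
        raise CountMatrixError(
            f"features.tsv rows ({len(features)}) != matrix rows ({mat.shape[0]})"
        )
    if len(barcodes) != mat.shape[1]:
        raise CountMatrixError(
            f"barcodes.tsv rows ({len(barcodes)}) != matrix columns ({mat.shape[1]})"
        )
    name_col = 1 if features.shape[1] > 1 else 0
    meta = None
    cells_path = path / "cells.tsv"
    if cells_path.exists():
        meta = pd.read_csv(cells_path, sep="\t", index_col="barcode")
    return CountMatrix(
        counts=sp.csr_matrix(mat),
        genes=pd.Index(features[name_col].astype(str)),
        cells=pd.Index(barcodes.astype(str)),
        cell_meta=meta,
    )


def _read_dense_tsv(path: Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if not np.allclose(values, np.round(values)):
        raise CountMatrixError("dense TSV contains non-integer entries")
    return CountMatrix(
        counts=sp.csr_matrix(values.astype(np.int64)),
        genes=pd.Index(df.index.astype(str)),
        cells=pd.Index(df.columns.astype(str)),
    )


def compute_qc(cm: CountMatrix, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell QC metrics: n_genes, n_umis, mito_frac.

    Cells with zero total counts get ``mito_frac`` 0 (with a warning).
    """
    counts = cm.counts.tocsc()
    n_genes = np.asarray((counts > 0).sum(axis=0)).ravel()
    n_umis = np.asarray(counts.sum(axis=0)).ravel()
    is_mito = cm.genes.str.startswith(mito_prefix)
    mito_umis = np.asarray(counts[np.flatnonzero(is_mito)].sum(axis=0)).ravel()
    zero = n_umis == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cells have zero counts; mito_frac set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(zero, 0.0, mito_umis / np.maximum(n_umis, 1))
    return pd.DataFrame(
        {"n_genes": n_genes.astype(int), "n_umis": n_umis.astype(int), "mito_frac": mito_frac},
        index=cm.cells,
    )


def filter_cells(
    cm: CountMatrix, metrics: pd.DataFrame, thresholds: QCThresholds
) -> tuple[CountMatrix, pd.Index, pd.DataFrame]:
    """Apply droplet QC thresholds; returns (filtered matrix, kept barcodes, report).

    The report lists, per criterion, how many cells failed it (a cell can
    fail several), plus the total removed.
    """
    metrics = metrics.loc[cm.cells]
    fails = {
        "low_n_genes": metrics["n_genes"] < thresholds.min_genes,
        "high_n_genes": (
            metrics["n_genes"] > thresholds.max_genes
            if thresholds.max_genes is not None
            else pd.Series(False, index=cm.cells)
        ),
        "low_n_umis": (
            metrics["n_umis"] < thresholds.min_umis
            if thresholds.min_umis is not None
            else pd.Series(False, index=cm.cells)
        ),
        "high_n_umis": (
            metrics["n_umis"] > thresholds.max_umis
            if thresholds.max_umis is not None
            else pd.Series(False, index=cm.cells)
        ),
        "high_mito_frac": metrics["mito_frac"] > thresholds.max_mito_frac,
    }
    any_fail = pd.Series(False, index=cm.cells)
    for mask in fails.values():
        any_fail |= mask
    kept = cm.cells[~any_fail.to_numpy()]
    if len(kept) == 0:
        raise EmptyResultError("QC thresholds removed every cell")
    report = pd.DataFrame(
        {"criterion": list(fails) + ["removed_total"],
         "n_removed": [int(m.sum()) for m in fails.values()] + [int(any_fail.sum())]}
    )
    return cm.subset_cells(kept), kept, report


def infer_sex(
    cm: CountMatrix,
    sex_gene: str = "SRY",
    sample_col: str = "sample",
    min_cells: int = 3,
) -> pd.Series:
    """Label each sample male/female by detection of a male-specific gene.

    A sample is called male when the gene is detected (count > 0) in at
    least ``min_cells`` of its cells.
    """
    if sex_gene not in cm.genes:
        raise KeyError(f"sex gene {sex_gene!r} not in gene list")
    if sample_col not in cm.cell_meta.columns:
        raise KeyError(f"cell_meta lacks a {sample_col!r} column")
    expr = cm.gene_vector(sex_gene) > 0
    detected = pd.Series(expr, index=cm.cells).groupby(cm.cell_meta[sample_col]).sum()
    labels = detected.apply(lambda n: "male" if n >= min_cells else "female")
    labels.name = "sex"
    return labels
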