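"""Sparse count-matrix I/O, barcode quality control, and normalizations.

Matrices are stored gene x cell throughout (rows are genes, columns are
cell barcodes), mirroring the MatrixMarket + sidecar layout produced by
droplet-based pipelines: ``matrix.mtx`` (1-based coordinate triplets),
``features.tsv`` (gene_id, gene_name) and ``barcodes.tsv``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

MATRIX_FILE = "matrix.mtx"
FEATURES_FILE = "features.tsv"
BARCODES_FILE = "barcodes.tsv"
METADATA_FILE = "cell_metadata.tsv"
TRUTH_FILE = "truth.tsv"

DEFAULT_MITO_PREFIX = "MT-"


class MatrixFormatError(ValueError):
    """Raised when on-disk matrix files are inconsistent or malformed."""


@dataclass
class CountMatrix:
    """Gene x cell matrix of nonnegative integer counts.

    Parameters
    ----------
    genes
        Ordered gene identifiers (rows). Must be unique.
    cells
        Ordered cell barcodes (columns). Must be unique.
    counts
        ``scipy.sparse`` matrix of shape ``(len(genes), len(cells))`` with
        nonnegative integral entries.
    gene_names
        Optional display names parallel to ``genes`` (defaults to ``genes``).
    """

    genes: np.ndarray
    cells: np.ndarray
    counts: sp.csr_matrix
    gene_names: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.cells = np.asarray(self.cells, dtype=object)
        if self.gene_names is None:
            self.gene_names = self.genes.copy()
        else:
            self.gene_names = np.asarray(self.gene_names, dtype=object)
        if len(np.unique(self.genes)) != len(self.genes):
            raise MatrixFormatError("duplicate gene identifiers")
        if len(np.unique(self.cells)) != len(self.cells):
            raise MatrixFormatError("duplicate cell barcodes")
        counts = sp.csr_matrix(self.counts)
        if counts.shape != (len(self.genes), len(self.cells)):
            raise MatrixFormatError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if counts.nnz and counts.data.min() < 0:
            raise MatrixFormatError("negative counts")
        if counts.nnz and np.any(counts.data != np.round(counts.data)):
            raise MatrixFormatError("non-integer counts")
        counts.eliminate_zeros()
        self.counts = counts

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_index(self, gene_ids) -> np.ndarray:
        """Row indices of ``gene_ids``; raises KeyError on missing genes."""
        lookup = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in gene_ids if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def subset_genes(self, row_idx: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.genes[row_idx],
            self.cells,
            self.counts[row_idx, :],
            gene_names=self.gene_names[row_idx],
        )

    def subset_cells(self, col_idx: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.genes,
            self.cells[col_idx],
            self.counts[:, col_idx],
            gene_names=self.gene_names,
        )


@dataclass
class QcThresholds:
    """Barcode-filtering rules.

    A cell is removed when it has fewer than ``min_genes_detected`` genes
    with nonzero counts, more than ``max_umi`` total transcripts, or a
    mitochondrial transcript fraction strictly greater than
    ``max_mito_fraction``. Mitochondrial genes are recognized by gene-name
    prefix.
    """

    min_genes_detected: int = 3000
    max_umi: int = 100_000
    max_mito_fraction: float = 0.01
    mito_prefix: str = DEFAULT_MITO_PREFIX

    def __post_init__(self) -> None:
        if self.min_genes_detected < 0:
            raise ValueError("min_genes_detected must be >= 0")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def write_matrix(m: CountMatrix, out_dir: str | os.PathLike) -> None:
    """Write ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``."""
    os.makedirs(out_dir, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(out_dir, MATRIX_FILE), sp.coo_matrix(m.counts), field="integer"
    )
    pd.DataFrame({"gene_id": m.genes, "gene_name": m.gene_names}).to_csv(
        os.path.join(out_dir, FEATURES_FILE), sep="\t", header=False, index=False
    )
    pd.Series(m.cells).to_csv(
        os.path.join(out_dir, BARCODES_FILE), sep="\t", header=False, index=False
    )


def read_matrix(in_dir: str | os.PathLike) -> CountMatrix:
    """Read a matrix directory written by :func:`write_matrix`.

    Sidecar ordering is preserved. Dimension mismatches between the
    MatrixMarket header and the sidecar files are hard errors, as are
    non-integer entries; explicit zeros are dropped.
    """
    mtx_path = os.path.join(in_dir, MATRIX_FILE)
    counts = scipy.io.mmread(mtx_path)
    feats = pd.read_csv(
        os.path.join(in_dir, FEATURES_FILE), sep="\t", header=None, dtype=str
    )
    try:
        barcodes = pd.read_csv(
            os.path.join(in_dir, BARCODES_FILE), sep="\t", header=None, dtype=str
        )[0].to_numpy()
    except pd.errors.EmptyDataError:
        barcodes = np.array([], dtype=object)
    if counts.shape[0] != len(feats):
        raise MatrixFormatError(
            f"header says {counts.shape[0]} genes but features.tsv has {len(feats)}"
        )
    if counts.shape[1] != len(barcodes):
        raise MatrixFormatError(
            f"header says {counts.shape[1]} cells but barcodes.tsv has {len(barcodes)}"
        )
    gene_ids = feats[0].to_numpy()
    gene_names = feats[1].to_numpy() if feats.shape[1] > 1 else gene_ids
    return CountMatrix(gene_ids, barcodes, sp.csr_matrix(counts), gene_names=gene_names)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_report(m: CountMatrix, thresholds: QcThresholds | None = None) -> pd.DataFrame:
    """Per-cell QC metrics and pass/fail flags for each rule.

    Mitochondrial fractions are computed on raw counts over all genes,
    before any gene filtering.
    """
    t = thresholds or QcThresholds()
    counts = m.counts.tocsc()
    total_umi = np.asarray(counts.sum(axis=0)).ravel()
    genes_detected = counts.getnnz(axis=0)
    is_mito = np.array(
        [str(name).startswith(t.mito_prefix) for name in m.gene_names], dtype=bool
    )
    mito_umi = (
        np.asarray(counts[is_mito, :].sum(axis=0)).ravel()
        if is_mito.any()
        else np.zeros(m.n_cells)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(total_umi > 0, mito_umi / total_umi, 0.0)
    # strict inequalities: "fewer than", "more than", "greater than"
    fail_genes = genes_detected < t.min_genes_detected
    fail_umi = total_umi > t.max_umi
    fail_mito = mito_fraction > t.max_mito_fraction
    return pd.DataFrame(
        {
            "barcode": m.cells,
            "genes_detected": genes_detected,
            "total_umi": total_umi.astype(int),
            "mito_fraction": mito_fraction,
            "fail_min_genes": fail_genes,
            "fail_max_umi": fail_umi,
            "fail_max_mito": fail_mito,
            "pass_qc": ~(fail_genes | fail_umi | fail_mito),
        }
    )


def qc_filter(
    m: CountMatrix, thresholds: QcThresholds | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove cells failing any QC rule; returns the kept matrix + report."""
    report = qc_report(m, thresholds)
    keep = np.flatnonzero(report["pass_qc"].to_numpy())
    return m.subset_cells(keep), report


# ---------------------------------------------------------------------------
# normalizations
# ---------------------------------------------------------------------------

def cpm(counts_vector: np.ndarray) -> np.ndarray:
    """Counts-per-million scaling of one library's count vector."""
    v = np.asarray(counts_vector, dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError("cannot compute CPM for a zero-total library")
    return v / total * 1e6


def percell_normalize(
    m: CountMatrix, target: float | None = None
) -> tuple[sp.csr_matrix, float]:
    """Scale every cell to a common total (median cell total by default).

    Returns the normalized (float) gene x cell matrix and the target used.
    """
    totals = np.asarray(m.counts.sum(axis=0)).ravel()
    if np.any(totals <= 0):
        raise ValueError("zero-total cell encountered; run QC first")
    if target is None:
        target = float(np.median(totals))
    scale = target / totals
    return m.counts.multiply(scale[np.newaxis, :]).tocsr(), target


def percell_normalize_sqrt(
    m: CountMatrix, target: float | None = None
) -> sp.csr_matrix:
    """Per-cell normalization followed by an elementwise square root.

    The square-root transform stabilizes count variance; applying it twice
    is not idempotent (values change on every application).
    """
    normalized, _ = percell_normalize(m, target=target)
    return normalized.sqrt().tocsr()


def gene_min_count_filter(m: CountMatrix, min_total: int = 10) -> CountMatrix:
    """Keep genes with at least ``min_total`` transcripts over all cells."""
    totals = np.asarray(m.counts.sum(axis=1)).ravel()
    keep = np.flatnonzero(totals >= min_total)
    return m.subset_genes(keep)
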