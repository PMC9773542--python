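"""Single-cell RNA-seq quality-control filtering over sparse count matrices.

Cells are retained when their number of detected gene features lies in an
inclusive band (default 2000-7500) and their mitochondrial read fraction is
strictly below a cap (default 10 %); genes are then retained when expressed
in at least a minimum number of the *retained* cells (default 10). The cell
filter is applied before the gene filter, and mitochondrial genes are
recognized by the human "MT-" name prefix (case-insensitive).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

__all__ = [
    "CellMatrix",
    "QCReport",
    "QCThresholds",
    "EmptyResultError",
    "FormatError",
    "read_10x_matrix",
    "write_10x_matrix",
    "qc_filter",
]


class FormatError(ValueError):
    """On-disk matrix triplet is inconsistent or incomplete."""


class EmptyResultError(RuntimeError):
    """QC removed every cell."""


@dataclass(frozen=True)
class QCThresholds:
    min_features: int = 2000     # inclusive
    max_features: int = 7500     # inclusive
    max_mito: float = 0.10       # strict upper bound on the mito fraction
    min_cells_per_gene: int = 10


@dataclass(frozen=True)
class CellMatrix:
    """Sparse non-negative integer count matrix, genes x cells, with names."""

    counts: sparse.spmatrix
    gene_ids: List[str]
    barcodes: List[str]

    def __post_init__(self) -> None:
        counts = sparse.csr_matrix(self.counts)
        if counts.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} cells")
        if counts.nnz and counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "gene_ids", list(self.gene_ids))
        object.__setattr__(self, "barcodes", list(self.barcodes))

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def mito_flag(self) -> np.ndarray:
        """Boolean per-gene flag: name starts with 'MT-' (case-insensitive)."""
        return np.array([g.upper().startswith("MT-") for g in self.gene_ids])


@dataclass(frozen=True)
class QCReport:
    """Per-cell/per-gene QC quantities and the retained index sets."""

    n_features: np.ndarray        # detected features per cell (count > 0)
    mito_fraction: np.ndarray     # mito counts / total counts per cell
    cells_per_gene: np.ndarray    # retained cells expressing each gene
    kept_cells: np.ndarray        # indices into the input barcodes
    kept_genes: np.ndarray        # indices into the input gene_ids
    thresholds: QCThresholds

    def cell_frame(self, barcodes: Sequence[str]) -> pd.DataFrame:
        kept = np.zeros(len(barcodes), dtype=bool)
        kept[self.kept_cells] = True
        return pd.DataFrame({
            "barcode": list(barcodes),
            "n_features": self.n_features,
            "mito_fraction": self.mito_fraction,
            "kept": kept,
        })


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "r")


def _find_file(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = directory / f"{stem}{suffix}"
            if p.exists():
                return p
    raise FormatError(f"none of {list(stems)} found in {directory}")


def _read_names(path: Path) -> List[str]:
    names = []
    with _open_maybe_gz(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            # 10x features.tsv: gene_id <tab> gene_symbol <tab> type — prefer the symbol
            names.append(parts[1] if len(parts) >= 2 else parts[0])
    return names


def read_10x_matrix(directory) -> CellMatrix:
    """Read a MatrixMarket + barcodes + features triplet (plain or gzipped).

    Orientation is normalized to genes x cells; a transposed matrix is
    auto-detected from the name counts and corrected. Dimensions that match
    neither orientation raise :class:`FormatError`.
    """
    directory = Path(directory)
    mtx_path = _find_file(directory, ["matrix.mtx"])
    barcodes_path = _find_file(directory, ["barcodes.tsv"])
    features_path = _find_file(directory, ["features.tsv", "genes.tsv"])
    with _open_maybe_gz(mtx_path) as fh:
        counts = sparse.csr_matrix(mmread(fh))
    barcodes = [l.split("\t")[0] for l in _read_raw_lines(barcodes_path)]
    genes = _read_names(features_path)
    if counts.shape == (len(genes), len(barcodes)):
        pass
    elif counts.shape == (len(barcodes), len(genes)):
        counts = counts.T.tocsr()
    else:
        raise FormatError(
            f"matrix shape {counts.shape} matches neither {len(genes)} genes x "
            f"{len(barcodes)} cells nor its transpose")
    return CellMatrix(counts=counts, gene_ids=genes, barcodes=barcodes)


def _read_raw_lines(path: Path) -> List[str]:
    with _open_maybe_gz(path) as fh:
        return [l.rstrip("\n") for l in fh if l.strip()]


def write_10x_matrix(m: CellMatrix, directory) -> None:
    """Write a plain-text MatrixMarket triplet (matrix.mtx, barcodes.tsv, features.tsv)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(str(directory / "matrix.mtx"), sparse.coo_matrix(m.counts))
    (directory / "barcodes.tsv").write_text("\n".join(m.barcodes) + "\n")
    (directory / "features.tsv").write_text(
        "\n".join(f"{g}\t{g}\tGene Expression" for g in m.gene_ids) + "\n")


def qc_filter(
    m: CellMatrix,
    *,
    min_features: int = 2000,
    max_features: int = 7500,
    max_mito: float = 0.10,
    min_cells_per_gene: int = 10,
) -> Tuple[CellMatrix, QCReport]:
    """Apply the cell and gene QC filters; returns (filtered matrix, report).

    Cells are kept iff ``min_features <= detected features <= max_features``
    (inclusive bounds) and mito fraction ``< max_mito``; genes are then kept
    iff expressed (count > 0) in at least ``min_cells_per_gene`` retained
    cells. Raises :class:`EmptyResultError` if no cell survives.
    """
    counts = m.counts.tocsc()
    detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    totals = np.asarray(counts.sum(axis=0)).ravel()
    mito = m.mito_flag
    mito_counts = np.asarray(counts[mito].sum(axis=0)).ravel() if mito.any() else np.zeros(m.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    keep_cells = ((detected >= min_features) & (detected <= max_features)
                  & (mito_frac < max_mito))
    kept_cells = np.flatnonzero(keep_cells)
    if kept_cells.size == 0:
        raise EmptyResultError("QC filtering removed every cell")

    sub = counts[:, kept_cells]
    cells_per_gene = np.asarray((sub > 0).sum(axis=1)).ravel()
    kept_genes = np.flatnonzero(cells_per_gene >= min_cells_per_gene)

    filtered = CellMatrix(
        counts=sub[kept_genes].tocsr(),
        gene_ids=[m.gene_ids[i] for i in kept_genes],
        barcodes=[m.barcodes[i] for i in kept_cells],
    )
    report = QCReport(
        n_features=detected, mito_fraction=mito_frac, cells_per_gene=cells_per_gene,
        kept_cells=kept_cells, kept_genes=kept_genes,
        thresholds=QCThresholds(min_features, max_features, max_mito, min_cells_per_gene),
    )
    return filtered, report
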