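"""Reading, writing and partitioning raw droplet-by-gene count matrices.

The input to sEV-droplet identification is the *raw* (unfiltered) barcode
matrix produced upstream of cell calling: every valid barcode is present,
including the vast majority of cell-free droplets. This module reads the
10x-style MTX triplet layout (``matrix.mtx[.gz]``, ``barcodes.tsv[.gz]``,
``features.tsv[.gz]``) and AnnData ``.h5ad`` containers, and splits the
barcodes into cell-containing droplets, candidate cell-free droplets (the
ones scored by the EM), and vacant droplets.

Cell calling itself is not re-implemented here: when upstream cell calls are
available they are passed through; otherwise a simple total-UMI threshold
stands in.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

__all__ = [
    "DropletMatrix",
    "DropletPartition",
    "MatrixFormatError",
    "read_matrix",
    "write_matrix",
    "partition_droplets",
    "write_partition_tsv",
]


class MatrixFormatError(ValueError):
    """Raised when an on-disk matrix does not match its declared layout."""


@dataclass
class DropletMatrix:
    """Sparse droplet x gene count matrix with barcode and gene identifiers.

    Rows are droplets (barcodes), columns are genes. Counts are non-negative
    integers (UMI counts); both identifier lists are duplicate-free.
    """

    counts: sp.csr_matrix
    barcodes: list
    genes: list
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        self.barcodes = [str(b) for b in self.barcodes]
        self.genes = [str(g) for g in self.genes]
        n, g = self.counts.shape
        if len(self.barcodes) != n:
            raise MatrixFormatError(
                f"{len(self.barcodes)} barcodes for {n} matrix rows"
            )
        if len(self.genes) != g:
            raise MatrixFormatError(f"{len(self.genes)} genes for {g} matrix columns")
        if len(set(self.barcodes)) != n:
            raise ValueError("duplicate barcodes in droplet matrix")
        if len(set(self.genes)) != g:
            raise ValueError("duplicate gene identifiers in droplet matrix")
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise ValueError("negative entries in count matrix")
            if not np.allclose(data, np.round(data)):
                raise ValueError("non-integer entries in count matrix")
        self.counts.data = np.asarray(np.round(data), dtype=np.int64)

    @property
    def n_droplets(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def total_counts(self) -> np.ndarray:
        """Total UMIs per droplet."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def detected_gene_counts(self) -> np.ndarray:
        """Number of genes with at least one count, per droplet."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def subset_droplets(self, barcodes: Sequence[str]) -> "DropletMatrix":
        """Row-subset to the given barcodes, preserving their given order."""
        index = {b: i for i, b in enumerate(self.barcodes)}
        try:
            rows = [index[b] for b in barcodes]
        except KeyError as exc:
            raise KeyError(f"barcode not in matrix: {exc.args[0]}") from None
        return DropletMatrix(
            self.counts[rows, :], list(barcodes), list(self.genes), self.sample_id
        )

    def to_anndata(self):
        import anndata as ad

        return ad.AnnData(
            X=self.counts.copy(),
            obs=pd.DataFrame(index=pd.Index(self.barcodes, name="barcode")),
            var=pd.DataFrame(index=pd.Index(self.genes, name="gene")),
        )

    @classmethod
    def from_anndata(cls, adata, sample_id: str = "sample") -> "DropletMatrix":
        X = adata.X
        if not sp.issparse(X):
            X = sp.csr_matrix(np.asarray(X))
        return cls(X, list(adata.obs_names), list(adata.var_names), sample_id)


@dataclass
class DropletPartition:
    """Assignment of barcodes to cell / candidate cell-free / vacant classes."""

    cell_droplets: list
    candidate_free_droplets: list
    vacant_droplets: list = field(default_factory=list)
    filter_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.cell_droplets) & set(self.candidate_free_droplets)
        if overlap:
            raise ValueError(f"barcodes in both partitions: {sorted(overlap)[:5]}")


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _find_triplet_file(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            candidate = directory / name
            if candidate.exists():
                return candidate
    raise FileNotFoundError(
        f"none of {list(stems)} (optionally .gz) found in {directory}"
    )


def _read_mtx_dir(directory: Path, sample_id: str) -> DropletMatrix:
    mtx_path = _find_triplet_file(directory, ["matrix.mtx"])
    bc_path = _find_triplet_file(directory, ["barcodes.tsv"])
    # legacy 10x v2 calls the feature file genes.tsv
    ft_path = _find_triplet_file(directory, ["features.tsv", "genes.tsv"])

    with _open_maybe_gzip(mtx_path, "rb") as fh:
        try:
            mat = mmread(fh)
        except ValueError as exc:
            raise MatrixFormatError(f"{mtx_path}: {exc}") from exc
    barcodes = pd.read_csv(bc_path, sep="\t", header=None)[0].astype(str).tolist()
    features = pd.read_csv(ft_path, sep="\t", header=None)
    # features may carry 1-3 columns; prefer the gene-symbol column when present
    symbol_col = 1 if features.shape[1] >= 2 else 0
    genes = features[symbol_col].astype(str).tolist()

    mat = sp.csr_matrix(mat)
    if mat.shape == (len(genes), len(barcodes)):
        mat = mat.T.tocsr()  # 10x convention stores genes x barcodes
    elif mat.shape != (len(barcodes), len(genes)):
        raise MatrixFormatError(
            f"matrix shape {mat.shape} matches neither "
            f"(droplets={len(barcodes)}, genes={len(genes)}) nor its transpose"
        )
    return DropletMatrix(mat, barcodes, genes, sample_id)


def read_matrix(
    path, format: str = "auto", sample_id: Optional[str] = None
) -> DropletMatrix:
    """Read a raw droplet x gene matrix.

    Parameters
    ----------
    path
        MTX triplet directory (``format="mtx_dir"``) or AnnData ``.h5ad``
        file (``format="h5"``).
    format
        ``"mtx_dir"``, ``"h5"`` or ``"auto"`` (directory -> mtx_dir,
        file -> h5).
    sample_id
        Label attached to the matrix; defaults to the path stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input path does not exist: {path}")
    if format == "auto":
        format = "mtx_dir" if path.is_dir() else "h5"
    sid = sample_id if sample_id is not None else path.stem
    if format == "mtx_dir":
        return _read_mtx_dir(path, sid)
    if format == "h5":
        import anndata as ad

        return DropletMatrix.from_anndata(ad.read_h5ad(path), sid)
    raise ValueError(f"unknown format {format!r}")


def write_matrix(m: DropletMatrix, directory) -> Path:
    """Write an MTX triplet directory (uncompressed) for a droplet matrix."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(m.counts.T)  # genes x barcodes on disk
    mmwrite(str(directory / "matrix.mtx"), mat, field="integer")
    (directory / "barcodes.tsv").write_text("".join(b + "\n" for b in m.barcodes))
    (directory / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in m.genes)
    )
    return directory


def partition_droplets(
    m: DropletMatrix,
    min_genes: int = 5,
    umi_range_free: tuple = (30, 500),
    cell_calls: Optional[Sequence[str]] = None,
    cell_umi_min: Optional[float] = None,
) -> DropletPartition:
    """Split barcodes into cell, candidate cell-free, and vacant droplets.

    Candidate cell-free droplets are those with at least ``min_genes``
    detected genes and total UMI in ``[lo, hi)``; these are the droplets the
    EM later classifies into sEV-containing versus debris. Cells are taken
    from ``cell_calls`` (upstream cell calling) when provided, otherwise any
    droplet with total UMI >= ``cell_umi_min`` (default: ``hi``) is treated
    as a cell. Everything else is vacant.
    """
    lo, hi = umi_range_free
    if not lo < hi:
        raise ValueError(f"umi_range_free must satisfy lo < hi, got [{lo}, {hi})")
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    if cell_calls is None:
        if cell_umi_min is None:
            cell_umi_min = hi
        if cell_umi_min < hi:
            raise ValueError(
                "candidate cell-free UMI window overlaps the implied cell range: "
                f"hi={hi} > cell_umi_min={cell_umi_min}"
            )

    totals = m.total_counts()
    ngenes = m.detected_gene_counts()
    barcodes = np.asarray(m.barcodes, dtype=object)

    if cell_calls is not None:
        cell_set = set(cell_calls) & set(m.barcodes)
        is_cell = np.array([b in cell_set for b in barcodes])
    else:
        is_cell = totals >= cell_umi_min
    is_candidate = (
        ~is_cell & (ngenes >= min_genes) & (totals >= lo) & (totals < hi)
    )
    is_vacant = ~is_cell & ~is_candidate

    params = {
        "min_genes": int(min_genes),
        "umi_range_free": [float(lo), float(hi)],
        "cell_calls_provided": cell_calls is not None,
        "cell_umi_min": None if cell_calls is not None else float(cell_umi_min),
    }
    part = DropletPartition(
        cell_droplets=list(barcodes[is_cell]),
        candidate_free_droplets=list(barcodes[is_candidate]),
        vacant_droplets=list(barcodes[is_vacant]),
        filter_params=params,
    )
    logger.info(
        "partitioned %d droplets: %d cells, %d candidates, %d vacant",
        m.n_droplets,
        len(part.cell_droplets),
        len(part.candidate_free_droplets),
        len(part.vacant_droplets),
    )
    return part


def write_partition_tsv(partition: DropletPartition, path) -> Path:
    """Write a two-column TSV: barcode, class in {cell, candidate, vacant}."""
    path = Path(path)
    rows = (
        [(b, "cell") for b in partition.cell_droplets]
        + [(b, "candidate") for b in partition.candidate_free_droplets]
        + [(b, "vacant") for b in partition.vacant_droplets]
    )
    pd.DataFrame(rows, columns=["barcode", "class"]).to_csv(
        path, sep="\t", index=False
    )
    return path
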