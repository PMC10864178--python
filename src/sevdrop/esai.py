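"""sEV secretion activity: sample-level ESAI and per-cell-type ESAI_c.

ESAI (sEV secretion activity index) is the number of sEV-containing droplets
per cell-containing droplet in a sample. To deconvolve it to cell types,
each sEV droplet is traced back to a plausible source cell type by combining
two signals:

* **Similarity** — an sEV's transcriptional profile resembles its cell of
  origin, measured by counting cell types among its N nearest annotated
  cells in a joint PCA embedding of cells and sEV droplets (total-count
  normalization to 100, log1p, 50 components by default).
* **Biogenesis** — cell types differ in vesicle-biogenesis capacity,
  measured by the GSEA enrichment score (weighted Kolmogorov-Smirnov
  running sum, weight exponent 1) of an sEV-biogenesis gene set on each
  type's mean-expression gene ranking.

The source cell type is the argmax of the two terms after per-droplet
min-max normalization (their native scales — neighbor counts in [0, N],
enrichment in [-1, 1] — are incommensurate). An sEV whose best Similarity
falls below a floor (default 2 neighbors) stays unassigned. ESAI_c(ci) is
then the number of sEV droplets assigned to type ci divided by the number
of cells of type ci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree
from sklearn.decomposition import PCA

from .io_droplets import DropletMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DeconvolutionConfig",
    "DeconvolutionResult",
    "compute_esai",
    "embed_joint",
    "similarity",
    "enrichment_score",
    "biogenesis",
    "assign_source",
    "compute_esai_c",
    "deconvolve",
    "load_annotation",
    "load_gmt",
    "bundled_biogenesis_set",
]

UNASSIGNED = "unassigned"


@dataclass
class DeconvolutionConfig:
    """Tunables for tracing sEV droplets to source cell types.

    n_neighbors
        N, the number of nearest annotated cells polled per sEV droplet.
    min_similarity
        Floor on the best per-type neighbor count; below it the droplet is
        left unassigned.
    n_pcs
        Dimensionality of the joint PCA embedding.
    target_sum
        Per-droplet total after count normalization (droplets carry few
        UMIs, so a small fixed total keeps depth comparable).
    """

    n_neighbors: int = 10
    min_similarity: int = 2
    n_pcs: int = 50
    target_sum: float = 100.0

    def __post_init__(self) -> None:
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.min_similarity < 0:
            raise ValueError("min_similarity must be >= 0")
        if self.n_pcs < 2:
            raise ValueError("n_pcs must be >= 2")


@dataclass
class DeconvolutionResult:
    """Per-droplet source assignments plus the derived activity indices."""

    assignments: pd.Series  # sEV barcode -> cell type or UNASSIGNED
    similarity: pd.DataFrame  # sEV barcode x cell type neighbor counts
    biogenesis: pd.Series  # cell type -> enrichment score
    esai_c: pd.Series  # cell type -> ESAI_c
    esai: float
    n_unassigned: int

    def __post_init__(self) -> None:
        n_assigned = int((self.assignments != UNASSIGNED).sum())
        if n_assigned + self.n_unassigned != len(self.assignments):
            raise AssertionError("assignment conservation violated")


def compute_esai(n_sev: int, n_cells: int) -> float:
    """Sample-level ESAI: sEV-containing droplets per cell-containing droplet."""
    if n_cells < 1:
        raise ValueError("ESAI undefined: no cell-containing droplets")
    if n_sev < 0:
        raise ValueError("negative sEV droplet count")
    return n_sev / n_cells


def _normalize_log(counts: sp.spmatrix, target_sum: float) -> np.ndarray:
    X = np.asarray(counts.todense(), dtype=np.float64)
    totals = X.sum(axis=1, keepdims=True)
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals), where=totals > 0)
    return np.log1p(X * scale)


def embed_joint(
    cells: DropletMatrix,
    sevs: DropletMatrix,
    n_pcs: int = 50,
    target_sum: float = 100.0,
    random_state: int = 0,
):
    """Joint PCA coordinates for cells and sEV droplets.

    Both matrices must share the same gene list. Each droplet is normalized
    to ``target_sum`` total counts, log1p-transformed, and projected onto
    ``n_pcs`` principal components fitted on cells and sEV droplets jointly,
    so neighbor queries live in a single space. Returns
    ``(cell_coords, sev_coords)``.
    """
    if cells.genes != sevs.genes:
        raise ValueError("cells and sEV droplets must share one gene universe")
    n_total = cells.n_droplets + sevs.n_droplets
    if n_pcs >= min(n_total, cells.n_genes):
        raise ValueError(
            f"n_pcs={n_pcs} must be < min(droplets={n_total}, genes={cells.n_genes})"
        )
    X = np.vstack(
        [
            _normalize_log(cells.counts, target_sum),
            _normalize_log(sevs.counts, target_sum),
        ]
    )
    # exact solver: deterministic and invariant to droplet row order
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=random_state)
    coords = pca.fit_transform(X)
    return coords[: cells.n_droplets], coords[cells.n_droplets :]


def similarity(
    sev_coords: np.ndarray,
    cell_coords: np.ndarray,
    annotation: pd.Series,
    cell_barcodes: Sequence[str],
    n_neighbors: int = 10,
    sev_barcodes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Neighbor-count Similarity of each sEV droplet to each cell type.

    For each sEV droplet, the ``n_neighbors`` nearest *annotated* cells by
    Euclidean distance in the embedding are found with a k-d tree, and their
    cell-type labels tallied. Rows sum to ``n_neighbors``.
    """
    annotation = annotation.astype(str)
    cell_barcodes = list(cell_barcodes)
    annotated_idx = [i for i, b in enumerate(cell_barcodes) if b in annotation.index]
    if not annotated_idx:
        raise ValueError("no annotated cells available for the similarity query")
    n_annotated = len(annotated_idx)
    if n_neighbors > n_annotated:
        raise ValueError(
            f"n_neighbors={n_neighbors} exceeds {n_annotated} annotated cells"
        )
    coords = np.asarray(cell_coords)[annotated_idx]
    labels = annotation.loc[[cell_barcodes[i] for i in annotated_idx]].to_numpy()
    types = sorted(set(labels))
    tree = cKDTree(coords)
    sev_coords = np.atleast_2d(np.asarray(sev_coords))
    _, nn = tree.query(sev_coords, k=n_neighbors)
    nn = np.atleast_2d(nn)
    if n_neighbors == 1:
        nn = nn.reshape(-1, 1)
    type_index = {t: j for j, t in enumerate(types)}
    counts = np.zeros((sev_coords.shape[0], len(types)), dtype=int)
    for i in range(nn.shape[0]):
        for j in nn[i]:
            counts[i, type_index[labels[j]]] += 1
    if sev_barcodes is None:
        sev_barcodes = [f"sev{i}" for i in range(sev_coords.shape[0])]
    return pd.DataFrame(counts, index=pd.Index(sev_barcodes, name="barcode"), columns=types)


def enrichment_score(
    metric: np.ndarray, is_hit: np.ndarray, weight_exponent: float = 1.0
) -> float:
    """Weighted Kolmogorov-Smirnov GSEA enrichment score of a ranked list.

    ``metric`` is the ranking statistic already sorted in descending order;
    ``is_hit`` flags gene-set members at each rank. Hits advance the running
    sum proportionally to ``|metric|**weight_exponent`` (normalized over
    hits), misses retreat it by 1/(M - Nh); the score is the running-sum
    deviation of largest magnitude, signed, in [-1, 1]. If every hit has
    zero metric the hit weights fall back to uniform.
    """
    metric = np.asarray(metric, dtype=np.float64)
    is_hit = np.asarray(is_hit, dtype=bool)
    if metric.shape != is_hit.shape:
        raise ValueError("metric and is_hit must have the same length")
    n = metric.size
    n_hit = int(is_hit.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must be a proper, non-empty subset of the ranking")
    w = np.abs(metric) ** weight_exponent
    w_hit = np.where(is_hit, w, 0.0)
    total = w_hit.sum()
    if total == 0:
        w_hit = is_hit.astype(float)
        total = float(n_hit)
    p_hit = np.cumsum(w_hit) / total
    p_miss = np.cumsum(~is_hit) / (n - n_hit)
    running = p_hit - p_miss
    return float(running[np.argmax(np.abs(running))])


def biogenesis(
    cells: DropletMatrix,
    annotation: pd.Series,
    sev_go: Sequence[str],
    weight_exponent: float = 1.0,
) -> pd.Series:
    """Per-cell-type biogenesis capacity as a GSEA enrichment score.

    For each annotated cell type, genes are ranked by their mean expression
    across that type's cells (descending, ties broken lexically for
    determinism) and the enrichment score of the biogenesis gene set on the
    ranking is returned. Types with no annotated cell in the matrix are
    omitted with a warning.
    """
    annotation = annotation.astype(str)
    go = set(sev_go) & set(cells.genes)
    if not go:
        raise ValueError("biogenesis gene set disjoint from the gene universe")
    barcode_index = {b: i for i, b in enumerate(cells.barcodes)}
    genes_arr = np.asarray(cells.genes, dtype=object)
    is_hit_universe = np.array([g in go for g in cells.genes])
    scores = {}
    for ctype in sorted(set(annotation)):
        members = [b for b in annotation.index[annotation == ctype] if b in barcode_index]
        if not members:
            logger.warning("cell type %r has no cells in the matrix; omitted", ctype)
            continue
        rows = [barcode_index[b] for b in members]
        mean_expr = np.asarray(cells.counts[rows, :].mean(axis=0)).ravel()
        order = np.lexsort((genes_arr, -mean_expr))
        scores[ctype] = enrichment_score(
            mean_expr[order], is_hit_universe[order], weight_exponent
        )
    return pd.Series(scores, dtype=float).sort_index()


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v, dtype=float)
    return (v - lo) / (hi - lo)


def assign_source(
    sim: pd.Series, bio: pd.Series, min_similarity: int = 2
) -> Optional[str]:
    """Pick the source cell type for one sEV droplet, or ``None``.

    If the best Similarity is below ``min_similarity`` the droplet is not
    similar enough to any type and stays unassigned. Otherwise both terms
    are min-max normalized to [0, 1] (their raw scales are incommensurate)
    and the argmax of the sum is returned; ties go to the larger raw
    Similarity, then to lexical type order.
    """
    sim = sim.astype(float)
    bio = bio.reindex(sim.index)
    if bio.isna().any():
        missing = list(bio.index[bio.isna()])
        raise ValueError(f"biogenesis scores missing for types: {missing}")
    if sim.max() < min_similarity:
        return None
    combined = _minmax(sim.to_numpy()) + _minmax(bio.to_numpy())
    best = combined.max()
    tied = [t for t, c in zip(sim.index, combined) if c >= best - 1e-12]
    if len(tied) > 1:
        best_sim = max(sim[t] for t in tied)
        tied = sorted(t for t in tied if sim[t] == best_sim)
    return tied[0]


def compute_esai_c(assignments: pd.Series, annotation: pd.Series) -> pd.Series:
    """ESAI_c: per type, assigned sEV droplets over cells of that type."""
    annotation = annotation.astype(str)
    cells_per_type = annotation.value_counts()
    assigned = assignments[assignments != UNASSIGNED]
    bad = set(assigned) - set(cells_per_type.index)
    if bad:
        raise AssertionError(f"sEV assigned to types with no cells: {sorted(bad)}")
    sev_per_type = assigned.value_counts().reindex(cells_per_type.index, fill_value=0)
    return (sev_per_type / cells_per_type).sort_index()


def deconvolve(
    cells: DropletMatrix,
    sevs: DropletMatrix,
    annotation: pd.Series,
    sev_go: Sequence[str],
    config: Optional[DeconvolutionConfig] = None,
) -> DeconvolutionResult:
    """Full deconvolution: embed, poll neighbors, score biogenesis, assign.

    ``annotation`` maps cell barcodes to cell-type labels; unannotated cells
    are ignored in the neighbor poll but still counted nowhere (ESAI_c uses
    annotated cells only). Returns assignments, both score tables, ESAI_c,
    and the sample ESAI over annotated cells.
    """
    cfg = config or DeconvolutionConfig()
    annotation = annotation.astype(str)
    if sevs.n_droplets == 0:
        esai_c = pd.Series(0.0, index=sorted(set(annotation))).sort_index()
        return DeconvolutionResult(
            assignments=pd.Series(dtype=object),
            similarity=pd.DataFrame(columns=sorted(set(annotation))),
            biogenesis=pd.Series(dtype=float),
            esai_c=esai_c,
            esai=0.0,
            n_unassigned=0,
        )
    cell_coords, sev_coords = embed_joint(
        cells, sevs, n_pcs=cfg.n_pcs, target_sum=cfg.target_sum
    )
    sim = similarity(
        sev_coords,
        cell_coords,
        annotation,
        cells.barcodes,
        n_neighbors=cfg.n_neighbors,
        sev_barcodes=sevs.barcodes,
    )
    bio = biogenesis(cells, annotation, sev_go)
    sim = sim[[t for t in sim.columns if t in bio.index]]
    assignments = {}
    for barcode, row in sim.iterrows():
        src = assign_source(row, bio, min_similarity=cfg.min_similarity)
        assignments[barcode] = UNASSIGNED if src is None else src
    assignments = pd.Series(assignments, dtype=object).reindex(sevs.barcodes)
    n_unassigned = int((assignments == UNASSIGNED).sum())
    esai_c = compute_esai_c(assignments, annotation)
    n_annotated_cells = int(annotation.index.isin(cells.barcodes).sum())
    esai = compute_esai(sevs.n_droplets, n_annotated_cells)
    return DeconvolutionResult(
        assignments=assignments,
        similarity=sim,
        biogenesis=bio,
        esai_c=esai_c,
        esai=esai,
        n_unassigned=n_unassigned,
    )


def load_annotation(path) -> pd.Series:
    """Read a two-column TSV (barcode, cell_type), optional header."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"annotation file needs two columns: {path}")
    first = df.iloc[0]
    if str(first[0]).lower() in ("barcode", "cell", "cell_id"):
        df = df.iloc[1:]
    series = pd.Series(df[1].values, index=df[0].values, name="cell_type")
    if series.index.duplicated().any():
        raise ValueError("duplicate barcodes in annotation")
    if (series.str.len() == 0).any():
        raise ValueError("empty cell-type labels in annotation")
    return series


def load_gmt(path) -> dict:
    """Read a GMT gene-set file: name, description, then gene symbols."""
    path = Path(path)
    sets = {}
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line in {path}: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    if not sets:
        raise ValueError(f"no gene sets in GMT file: {path}")
    return sets


def bundled_biogenesis_set() -> list:
    """The packaged sEV-biogenesis gene set (synthetic placeholder).

    A small synthetic stand-in for an MSigDB vesicle-biogenesis set; real
    analyses should pass their own GMT via :func:`load_gmt`.
    """
    ref = resources.files("sevdrop").joinpath("data", "sev_biogenesis_synthetic.gmt")
    with resources.as_file(ref) as path:
        sets = load_gmt(path)
    return next(iter(sets.values()))
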