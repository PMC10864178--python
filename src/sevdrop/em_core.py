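"""The EM identifier for sEV-containing droplets.

A droplet that captured small-extracellular-vesicle RNA shows an excess of
sEV-associated transcripts among its (few) detected genes, relative to a
debris droplet that sampled ambient cellular RNA. The identifier encodes
this as a latent per-droplet signal score Z_n and alternates two steps:

* **E-step** — with the current representative gene set theta, each
  candidate cell-free droplet is scored by the hypergeometric upper tail of
  its overlap with theta: k_n signature genes detected out of N_n detected
  genes, in a universe of M genes of which theta_N are signature. The score
  is Z_n = -log10(p), the enrichment surprise.

* **M-step** — the gene set is refitted to the data: every gene is ranked by
  the Spearman correlation of its counts (across candidate droplets) with
  Z, and the top K = a x base_size genes become the next theta. The factor
  ``a`` (default 10) controls the length of theta.

Iteration stops when consecutive gene sets agree (Jaccard >= 0.95 by
default). The final Z is the droplet's sEV signal score; droplets whose
Benjamini-Hochberg-adjusted enrichment p-value falls below alpha are called
sEV-containing, the rest debris. The EM itself is deterministic: identical
inputs give identical gene-set traces and calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import hypergeom, rankdata
from statsmodels.stats.multitest import multipletests

from .gene_set import SEVGeneSet
from .io_droplets import DropletMatrix, DropletPartition

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetState",
    "EnrichmentResult",
    "SEVCallResult",
    "binarize",
    "e_step",
    "m_step",
    "spearman_by_gene",
    "jaccard",
    "run_em",
    "write_scores_tsv",
]

#: floor applied to p-values before -log10 so scores stay finite
P_FLOOR = 1e-300


@dataclass
class GeneSetState:
    """The representative sEV gene set theta at one EM iteration."""

    theta: list
    a: int = 10
    base_size: int = 10
    iteration: int = 0

    def __post_init__(self) -> None:
        if len(self.theta) < 1:
            raise ValueError("theta must contain at least one gene")
        if len(set(self.theta)) != len(self.theta):
            raise ValueError("theta contains duplicates")
        if self.a < 1:
            raise ValueError("length factor a must be >= 1")

    @property
    def theta_N(self) -> int:
        return len(self.theta)

    @property
    def target_size(self) -> int:
        """K, the theta length targeted by the M-step (a x base_size)."""
        return self.a * self.base_size


@dataclass
class EnrichmentResult:
    """Per-droplet hypergeometric enrichment of the current gene set.

    ``table`` is indexed by barcode with columns ``k`` (signature genes
    detected), ``N`` (genes detected), ``p_raw``, ``p_adj`` (BH across the
    scored droplets) and ``score`` (Z = -log10 p_raw, floored).
    """

    table: pd.DataFrame
    M: int
    theta_N: int


@dataclass
class SEVCallResult:
    """Converged identifier output for one sample."""

    scores: pd.DataFrame  # barcode-indexed: k, N, p_raw, p_adj, score, sev_call
    state: GeneSetState
    trace: pd.DataFrame  # per iteration: theta_size, jaccard_to_prev, mean_score
    converged: bool
    sample_id: str = "sample"

    @property
    def sev_barcodes(self) -> list:
        return list(self.scores.index[self.scores["sev_call"]])


def binarize(m) -> sp.csr_matrix:
    """Detection indicator: 1 where a count is positive, 0 elsewhere."""
    counts = m.counts if isinstance(m, DropletMatrix) else m
    if not sp.issparse(counts):
        counts = sp.csr_matrix(np.asarray(counts))
    det = (counts > 0).astype(np.int8).tocsr()
    det.eliminate_zeros()
    return det


def e_step(
    det: sp.spmatrix,
    genes: Sequence[str],
    state: GeneSetState,
    barcodes: Optional[Sequence[str]] = None,
) -> EnrichmentResult:
    """Score droplets by hypergeometric enrichment of the current theta.

    ``det`` is the detection indicator over candidate droplets (rows) and
    the full gene universe (columns). For each droplet the upper-tail
    p-value P(X >= k_n) with X ~ Hypergeometric(M, theta_N, N_n) measures
    how surprising the observed signature overlap is; Z_n = -log10(p).
    """
    det = sp.csr_matrix(det)
    genes = list(genes)
    M = len(genes)
    if det.shape[1] != M:
        raise ValueError(f"detection matrix has {det.shape[1]} columns, {M} genes")
    gene_index = {g: i for i, g in enumerate(genes)}
    theta_idx = [gene_index[g] for g in state.theta if g in gene_index]
    if not theta_idx:
        raise ValueError("gene set disjoint from dataset")
    theta_N = len(theta_idx)

    N = np.asarray(det.sum(axis=1)).ravel()
    k = np.asarray(det[:, theta_idx].sum(axis=1)).ravel()
    # P(X >= k) = sf(k - 1) for X ~ Hypergeometric(M, theta_N, N_n)
    p_raw = hypergeom.sf(k - 1, M, theta_N, N)
    p_raw = np.clip(p_raw, 0.0, 1.0)
    score = -np.log10(np.maximum(p_raw, P_FLOOR))
    if len(p_raw):
        p_adj = multipletests(p_raw, method="fdr_bh")[1]
    else:
        p_adj = p_raw
    if barcodes is None:
        barcodes = [f"droplet{i}" for i in range(det.shape[0])]
    table = pd.DataFrame(
        {
            "k": k.astype(int),
            "N": N.astype(int),
            "p_raw": p_raw,
            "p_adj": p_adj,
            "score": score,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    return EnrichmentResult(table=table, M=M, theta_N=theta_N)


def spearman_by_gene(X, z: np.ndarray) -> np.ndarray:
    """Spearman rank correlation of each gene (column of X) with z.

    Ties receive average ranks; genes with zero rank variance get rho = 0.
    """
    if sp.issparse(X):
        X = X.toarray()
    X = np.asarray(X, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    if X.shape[0] != z.shape[0]:
        raise ValueError("row count of X must match length of z")
    rx = rankdata(X, axis=0)
    rz = rankdata(z)
    rx_c = rx - rx.mean(axis=0, keepdims=True)
    rz_c = rz - rz.mean()
    num = rx_c.T @ rz_c
    denom = np.sqrt((rx_c**2).sum(axis=0) * (rz_c**2).sum())
    rho = np.zeros(X.shape[1])
    ok = denom > 0
    rho[ok] = num[ok] / denom[ok]
    return rho


def m_step(
    counts, genes: Sequence[str], z: np.ndarray, state: GeneSetState
) -> GeneSetState:
    """Refit theta to the genes most rank-correlated with the latent score.

    Returns the top K = a x base_size genes by Spearman rho (descending),
    ties broken by gene-symbol lexical order for determinism. If z is
    constant there is nothing to rank against; the state is returned
    unchanged with a warning.
    """
    genes = list(genes)
    z = np.asarray(z, dtype=np.float64)
    n = z.shape[0]
    if n < 3:
        raise ValueError("insufficient cell-free droplets for the M-step (need >= 3)")
    if np.allclose(z, z[0]):
        logger.warning("latent score is constant; gene set left unchanged")
        return GeneSetState(
            list(state.theta), a=state.a, base_size=state.base_size,
            iteration=state.iteration + 1,
        )
    rho = spearman_by_gene(counts, z)
    genes_arr = np.asarray(genes, dtype=object)
    order = np.lexsort((genes_arr, -rho))  # rho desc, then symbol asc
    K = min(state.target_size, len(genes))
    new_theta = list(genes_arr[order[:K]])
    return GeneSetState(
        new_theta, a=state.a, base_size=state.base_size,
        iteration=state.iteration + 1,
    )


def jaccard(a: Sequence[str], b: Sequence[str]) -> float:
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        return 1.0
    return len(sa & sb) / len(union)


def run_em(
    m: DropletMatrix,
    partition: DropletPartition,
    seed_set: SEVGeneSet,
    a: int = 10,
    base_size: int = 10,
    max_iter: int = 20,
    converge_jaccard: float = 0.95,
    alpha: float = 0.05,
) -> SEVCallResult:
    """Run the EM on one sample's candidate cell-free droplets.

    theta is initialized to the seed gene set intersected with the sample's
    gene universe, then E- and M-steps alternate until consecutive gene sets
    reach the Jaccard convergence threshold or ``max_iter`` is hit (the
    latter returns the last state with a warning, not an error). The final
    E-step's Z is the sEV signal score; droplets with BH-adjusted p < alpha
    are called sEV-containing.
    """
    candidates = list(partition.candidate_free_droplets)
    if len(candidates) < 3:
        raise ValueError(
            f"insufficient cell-free droplets: {len(candidates)} candidates (need >= 3)"
        )
    sub = m.subset_droplets(candidates)
    universe = set(sub.genes)
    theta0 = [g for g in seed_set.genes if g in universe]
    n_dropped = len(seed_set.genes) - len(theta0)
    if n_dropped:
        logger.info(
            "%d/%d seed genes absent from the dataset and dropped",
            n_dropped, len(seed_set.genes),
        )
    if not theta0:
        raise ValueError("gene set disjoint from dataset")

    det = binarize(sub)
    state = GeneSetState(theta0, a=a, base_size=base_size, iteration=0)
    trace_rows = []
    converged = False
    enr = None
    for _ in range(max_iter):
        enr = e_step(det, sub.genes, state, barcodes=candidates)
        new_state = m_step(sub.counts, sub.genes, enr.table["score"].to_numpy(), state)
        jac = jaccard(new_state.theta, state.theta)
        trace_rows.append(
            {
                "iteration": new_state.iteration,
                "theta_size": new_state.theta_N,
                "jaccard_to_prev": jac,
                "mean_score": float(enr.table["score"].mean()),
            }
        )
        logger.debug(
            "iteration %d: |theta|=%d jaccard=%.3f mean Z=%.3f",
            new_state.iteration, new_state.theta_N, jac,
            trace_rows[-1]["mean_score"],
        )
        state = new_state
        if jac >= converge_jaccard:
            converged = True
            break
    if not converged:
        logger.warning(
            "gene set did not converge within %d iterations (last Jaccard %.3f)",
            max_iter, trace_rows[-1]["jaccard_to_prev"] if trace_rows else float("nan"),
        )
    # final scoring pass with the converged (or last) gene set
    enr = e_step(det, sub.genes, state, barcodes=candidates)
    scores = enr.table.copy()
    scores["sev_call"] = scores["p_adj"] < alpha
    trace = pd.DataFrame(
        trace_rows,
        columns=["iteration", "theta_size", "jaccard_to_prev", "mean_score"],
    )
    return SEVCallResult(
        scores=scores, state=state, trace=trace, converged=converged,
        sample_id=m.sample_id,
    )


def write_scores_tsv(result: SEVCallResult, path) -> Path:
    path = Path(path)
    result.scores.to_csv(path, sep="\t")
    return path
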