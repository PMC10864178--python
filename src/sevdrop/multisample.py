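"""Cross-sample aggregation: voting on converged gene sets, unified rescoring.

Each sample's EM converges to its own representative gene set, so raw scores
are not directly comparable across samples. Two steps restore comparability:
genes are *voted* on (a gene enters the unified set when it occurs in more
than a majority fraction of the per-sample converged sets), and every sample
is then rescored with a single E-step against the unified set. No further
M-steps are run: the unified set is held fixed so the scores share one
reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .em_core import GeneSetState, SEVCallResult, binarize, e_step
from .gene_set import SEVGeneSet
from .io_droplets import DropletMatrix, DropletPartition

logger = logging.getLogger(__name__)

__all__ = ["VotingResult", "vote", "unify_scores"]


@dataclass
class VotingResult:
    """Outcome of majority voting across per-sample converged gene sets."""

    frequencies: pd.Series  # fraction of sample sets containing each union gene
    unified: list
    majority_frac: float
    n_samples: int


def vote(converged_sets: Sequence[Sequence[str]], majority_frac: float = 0.5) -> VotingResult:
    """Build the unified gene set from per-sample converged sets.

    A gene is included when its occurrence frequency is *strictly greater*
    than ``majority_frac`` (default 0.5, i.e. a strict majority). The result
    is ordered by frequency (descending), ties broken lexically.
    """
    if len(converged_sets) < 1:
        raise ValueError("need at least one converged gene set")
    if not 0 < majority_frac <= 1:
        raise ValueError("majority_frac must be in (0, 1]")
    n = len(converged_sets)
    counts: dict = {}
    for s in converged_sets:
        for g in set(s):
            counts[g] = counts.get(g, 0) + 1
    if not counts:
        raise ValueError("union of converged gene sets is empty")
    freq = pd.Series(counts, dtype=float) / n
    freq = freq.sort_index().sort_values(ascending=False, kind="stable")
    unified = list(freq.index[freq > majority_frac])
    if not unified:
        logger.warning(
            "no gene exceeds the majority fraction %.2f across %d samples",
            majority_frac, n,
        )
    return VotingResult(
        frequencies=freq, unified=unified, majority_frac=majority_frac, n_samples=n
    )


def unify_scores(
    samples: Sequence[tuple],
    unified: Sequence[str],
    alpha: float = 0.05,
) -> list:
    """Rescore every sample with one E-step against the unified gene set.

    ``samples`` is a sequence of ``(DropletMatrix, DropletPartition)``
    pairs. Returns one :class:`SEVCallResult` per sample (``None`` for a
    sample whose gene universe is disjoint from the unified set, which is
    skipped with a warning). Calls are re-derived at the same alpha.
    """
    unified = list(unified)
    if not unified:
        raise ValueError("unified gene set is empty")
    results = []
    for m, partition in samples:
        candidates = list(partition.candidate_free_droplets)
        sub = m.subset_droplets(candidates)
        theta = [g for g in unified if g in set(sub.genes)]
        if not theta:
            logger.warning(
                "unified gene set disjoint from sample %s; skipped", m.sample_id
            )
            results.append(None)
            continue
        state = GeneSetState(theta, iteration=0)
        enr = e_step(binarize(sub), sub.genes, state, barcodes=candidates)
        scores = enr.table.copy()
        scores["sev_call"] = scores["p_adj"] < alpha
        results.append(
            SEVCallResult(
                scores=scores,
                state=state,
                trace=pd.DataFrame(
                    columns=["iteration", "theta_size", "jaccard_to_prev", "mean_score"]
                ),
                converged=True,
                sample_id=m.sample_id,
            )
        )
    return results
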