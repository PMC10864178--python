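"""Loading and synthesizing the sEV-associated gene set that seeds the EM.

The identifier is initialized with a curated list of transcripts known to be
enriched in small extracellular vesicles (the "SEV gene set", 2,017 genes in
the published curation). This module loads such a list from a plain-text
file, ships a synthetic placeholder fixture with the documented cardinality
(real analyses should supply the curated list for the right species), and
can draw surrogate gene sets from a dataset's own gene universe for
simulation studies.

Gene symbols are matched case-sensitively and exactly; no ortholog mapping
is attempted. Symbols absent from a dataset's gene universe are dropped (and
counted) at EM start-up, so every hypergeometric quantity lives in one
consistent universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SEVGeneSet",
    "load_gene_set",
    "write_gene_set",
    "bundled_gene_set",
    "make_surrogate_gene_set",
]

_BUNDLED_FIXTURE = "sev_gene_set_synthetic.txt"


@dataclass
class SEVGeneSet:
    """A duplicate-free, ordered list of sEV-associated gene symbols."""

    genes: list
    source: str = "curated"  # "curated" | "surrogate"
    species: str = "human"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene set is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene set contains duplicates")
        if self.source not in ("curated", "surrogate"):
            raise ValueError(f"unknown source {self.source!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


def _dedupe(symbols: Sequence[str]) -> list:
    seen = set()
    out = []
    dropped = 0
    for s in symbols:
        if s in seen:
            dropped += 1
            continue
        seen.add(s)
        out.append(s)
    if dropped:
        logger.warning("dropped %d duplicate gene symbols", dropped)
    return out


def load_gene_set(path, source: str = "curated", species: str = "human") -> SEVGeneSet:
    """Load a one-symbol-per-line gene list.

    Blank lines and ``#`` comment lines are skipped; a first line reading
    ``gene`` or ``symbol`` (any case) is treated as a header. Duplicates are
    removed with a logged warning, preserving first-occurrence order.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    symbols = []
    for i, raw in enumerate(lines):
        s = raw.strip()
        if not s or s.startswith("#"):
            continue
        if i == 0 and s.lower() in ("gene", "symbol", "gene_symbol"):
            continue
        symbols.append(s)
    if not symbols:
        raise ValueError(f"gene-set file is empty: {path}")
    return SEVGeneSet(_dedupe(symbols), source=source, species=species)


def write_gene_set(gene_set: SEVGeneSet, path) -> Path:
    path = Path(path)
    path.write_text("".join(g + "\n" for g in gene_set.genes))
    return path


def bundled_gene_set() -> SEVGeneSet:
    """The packaged sEV gene-set fixture.

    This is a *synthetic* placeholder: 2,017 unique symbols generated to
    match the cardinality of the published curation, not the curated symbols
    themselves. It exercises every code path that consumes a curated list;
    for analyses of real data, load the curated list with
    :func:`load_gene_set` instead.
    """
    ref = resources.files("sevdrop").joinpath("data", _BUNDLED_FIXTURE)
    with resources.as_file(ref) as path:
        return load_gene_set(path, source="curated", species="synthetic")


def make_surrogate_gene_set(
    n_genes: int, universe: Sequence[str], seed: int
) -> SEVGeneSet:
    """Sample a surrogate gene set from a gene universe, without replacement.

    Deterministic for a given seed; used to stand in for the curated list in
    simulation studies where the universe is synthetic.
    """
    universe = list(universe)
    if n_genes > len(universe):
        raise ValueError(
            f"cannot sample {n_genes} genes from a universe of {len(universe)}"
        )
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(universe), size=n_genes, replace=False)
    return SEVGeneSet([universe[i] for i in picked], source="surrogate")
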