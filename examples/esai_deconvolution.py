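"""Deconvolve sEV secretion activity (ESAI, ESAI_c) to source cell types.

Two separable cell types secrete sEVs at a planted 3:1 per-type rate. Each
sEV droplet is traced back by polling its nearest annotated cells in a joint
PCA embedding plus a biogenesis enrichment term; ESAI_c divides per-type sEV
counts by per-type cell counts.
"""

import numpy as np
import pandas as pd
import scipy.sparse as sp

from sevdrop import deconvolve
from sevdrop.io_droplets import DropletMatrix
from sevdrop.simulator import simulate_cell_droplets

rng = np.random.default_rng(7)
n_genes = 1000
base = rng.lognormal(0, 1.0, n_genes)
profile_a = base.copy()
idx_a = rng.choice(n_genes, 150, replace=False)
profile_a[idx_a] *= 5
profile_b = base.copy()
profile_b[rng.choice(np.setdiff1d(np.arange(n_genes), idx_a), 150, replace=False)] *= 5

cells, annotation = simulate_cell_droplets(
    {"A": profile_a, "B": profile_b}, n_per_type=150, umi_lambda=800, dropout=0.1, seed=8
)
# planted secretion: type A emits 90 sEV droplets, type B emits 30 (3:1 rate)
sev_a, _ = simulate_cell_droplets({"A": profile_a}, n_per_type=90, umi_lambda=100,
                                  dropout=0.3, seed=9, sample_id="sevA")
sev_b, _ = simulate_cell_droplets({"B": profile_b}, n_per_type=30, umi_lambda=100,
                                  dropout=0.3, seed=10, sample_id="sevB")
sevs = DropletMatrix(sp.vstack([sev_a.counts, sev_b.counts]),
                     sev_a.barcodes + sev_b.barcodes, sev_a.genes, "sevs")

biogenesis_set = [f"G{i:05d}" for i in rng.choice(n_genes, 30, replace=False)]
result = deconvolve(cells, sevs, annotation, biogenesis_set)

print(f"sample ESAI: {100 * result.esai:.1f}% "
      f"({sevs.n_droplets} sEV droplets / {cells.n_droplets} cells)")
for ctype, value in result.esai_c.items():
    print(f"ESAI_c[{ctype}] = {100 * value:.1f}%")
print(f"unassigned sEV droplets: {result.n_unassigned}")
print(f"recovered secretion ratio A:B = "
      f"{result.esai_c['A'] / result.esai_c['B']:.2f} (planted 3.0)")
# ESAI_c is per-type secretion activity: sEV droplets assigned to a type per
# cell of that type; the ratio recovers the planted 3:1 design.
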