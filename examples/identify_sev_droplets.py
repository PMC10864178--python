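"""Identify sEV-containing droplets in one simulated raw sample.

Simulates 2,000 cell-free droplets (20% drawn from an sEV expression
profile with a planted 100-gene signature), seeds the EM with a partially
overlapping surrogate gene set, and scores every droplet.
"""

from sklearn.metrics import roc_auc_score

from sevdrop import SimulationConfig, make_reference_profiles, run_em, simulate_droplets
from sevdrop.benchmark import surrogate_seed_set
from sevdrop.io_droplets import DropletPartition

ref = make_reference_profiles(n_genes=2000, n_signature=100, fold_up=4.0, seed=0)
cfg = SimulationConfig(seed=1)  # defaults: 2,000 droplets, UMI mean 150, 20% sEV
matrix, truth = simulate_droplets(cfg, ref)

# every simulated droplet is cell-free, so all of them are EM candidates
partition = DropletPartition(cell_droplets=[], candidate_free_droplets=list(matrix.barcodes))
seed_set = surrogate_seed_set(ref, n_planted=60, n_decoys=40, seed=2)

result = run_em(matrix, partition, seed_set)
auc = roc_auc_score((truth["truth"] == "sev").astype(int), result.scores["score"])
recovered = len(set(result.state.theta) & set(ref.signature_genes))

print(f"converged: {result.converged} after {len(result.trace)} iterations")
print(f"sEV calls (BH-adjusted p < 0.05): {int(result.scores['sev_call'].sum())} "
      f"of {matrix.n_droplets} droplets ({int((truth['truth'] == 'sev').sum())} truly sEV)")
print(f"ROC AUC of the sEV signal score vs truth: {auc:.3f}")
print(f"planted signature genes recovered in the converged set: {recovered}/100")
# The AUC measures how well the converged enrichment score separates
# sEV-containing from debris droplets; recovery shows the M-step replacing
# seed-set decoys with truly informative genes.
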