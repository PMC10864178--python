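# sevdrop

Droplet-based scRNA-seq libraries capture far more than cells: most valid
barcodes mark **cell-free droplets** — vacant, loaded with cellular debris,
or carrying the RNA cargo of **small extracellular vesicles (sEVs)**,
~30–150 nm vesicles that mediate cell–cell communication. sevdrop identifies
the sEV-containing droplets directly from the *raw* (pre cell-calling)
barcode matrix, quantifies each sample's **sEV secretion activity index
(ESAI)**, and deconvolves that activity to source cell types (**ESAI_c**).
It is aimed at computational biologists who want extracellular readouts from
ordinary scRNA-seq runs, with no extra bench work.

## Method

An sEV-containing droplet shows an excess of sEV-associated transcripts
among its detected genes. With a representative sEV gene set θ (θ_N genes in
a universe of M), a droplet detecting N_n genes of which k_n are in θ is
scored by the hypergeometric upper tail

    p_n = P(X ≥ k_n),  X ~ Hypergeometric(M, θ_N, N_n),   Z_n = −log10 p_n,

and θ itself is learned by expectation–maximization:

* **E-step** — score all candidate cell-free droplets with the current θ;
* **M-step** — rank every gene by the Spearman correlation ρ_g of its counts
  with Z across droplets and keep the top K = a × base_size genes
  (a = 10 by default, K = 100), ties broken lexically;
* iterate until consecutive gene sets agree (Jaccard ≥ 0.95), starting from
  a curated sEV gene list.

The final Z_n is the droplet's sEV signal score; droplets with
Benjamini–Hochberg-adjusted p < 0.05 are called sEV-containing. Across
samples, converged gene sets are **voted** (strict majority) into a unified
set and every sample is rescored against it so scores are comparable.

Secretion activity is `ESAI = #sEV droplets / #cell droplets`. For ESAI_c,
each sEV droplet polls its N = 10 nearest annotated cells in a joint PCA
embedding (Similarity), each cell type gets a GSEA enrichment score of an
sEV-biogenesis gene set on its mean-expression ranking (Biogenesis), and
`Source_Celltype = argmax(Similarity + Biogenesis)` after per-droplet
min-max normalization, with droplets below 2 same-type neighbors left
unassigned. `ESAI_c(ci) = #sEV assigned to ci / #cells of type ci`.

A ZINB-style simulator (Poisson droplet totals, per-gene zero inflation and
Gamma overdispersion, planted signature genes) provides labeled ground truth
and the 4×4 sEV-fraction × UMI-depth benchmark grid.

## Worked example

```bash
python examples/identify_sev_droplets.py
```

```
converged: True after 4 iterations
sEV calls (BH-adjusted p < 0.05): 386 of 2000 droplets (382 truly sEV)
ROC AUC of the sEV signal score vs truth: 0.996
planted signature genes recovered in the converged set: 93/100
```

2,000 simulated cell-free droplets (20% sEV, mean 150 UMIs) are scored from
a seed gene set that is only 60% correct; the EM recovers 93 of the 100
planted signature genes and the score separates sEV from debris droplets
with AUC 0.996. `examples/multi_sample_unification.py` shows cross-sample
voting, and `examples/esai_deconvolution.py` recovers a planted 3:1
per-type secretion ratio exactly (`ESAI_c[A] = 60.0%`, `ESAI_c[B] = 20.0%`).

The same pipeline is scriptable from the shell (`sevdrop simulate`,
`sevdrop identify`, `sevdrop esai`); run `sevdrop --help`.

Note: the bundled curated-list fixture (`sevdrop/data/sev_gene_set_synthetic.txt`)
is a synthetic placeholder with the documented cardinality (2,017 symbols);
analyses of real data should supply a curated sEV gene list for the species
at hand via `load_gene_set` / `--gene-set`.

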