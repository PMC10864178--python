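import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from sevdrop.esai import (
    UNASSIGNED,
    DeconvolutionConfig,
    assign_source,
    biogenesis,
    bundled_biogenesis_set,
    compute_esai,
    compute_esai_c,
    deconvolve,
    embed_joint,
    enrichment_score,
    load_annotation,
    load_gmt,
    similarity,
)
from sevdrop.io_droplets import DropletMatrix
from sevdrop.simulator import simulate_cell_droplets


# ---------------------------------------------------------------- fixtures
def two_type_system(seed=7, n_cells_per_type=150, n_sev=(90, 30)):
    """Two separable cell types plus sEV droplets drawn from their profiles
    at a planted 3:1 per-type secretion rate."""
    rng = np.random.default_rng(seed)
    G = 1000
    base = rng.lognormal(0, 1.0, G)
    prof_a = base.copy()
    idx_a = rng.choice(G, 150, replace=False)
    prof_a[idx_a] *= 5
    prof_b = base.copy()
    idx_b = rng.choice(np.setdiff1d(np.arange(G), idx_a), 150, replace=False)
    prof_b[idx_b] *= 5
    cells, ann = simulate_cell_droplets(
        {"A": prof_a, "B": prof_b}, n_per_type=n_cells_per_type,
        umi_lambda=800, dropout=0.1, seed=seed + 1,
    )
    sev_a, _ = simulate_cell_droplets(
        {"A": prof_a}, n_per_type=n_sev[0], umi_lambda=100, dropout=0.3,
        seed=seed + 2, sample_id="sevA",
    )
    sev_b, _ = simulate_cell_droplets(
        {"B": prof_b}, n_per_type=n_sev[1], umi_lambda=100, dropout=0.3,
        seed=seed + 3, sample_id="sevB",
    )
    sevs = DropletMatrix(
        sp.vstack([sev_a.counts, sev_b.counts]),
        sev_a.barcodes + sev_b.barcodes,
        sev_a.genes,
        "sevs",
    )
    truth = pd.Series(
        ["A"] * n_sev[0] + ["B"] * n_sev[1], index=sevs.barcodes
    )
    sev_go = [f"G{i:05d}" for i in rng.choice(G, 30, replace=False)]
    return cells, ann, sevs, truth, sev_go


@pytest.fixture(scope="module")
def two_type():
    return two_type_system()


# ---------------------------------------------------------------- ESAI
def test_esai_basic_values():
    assert compute_esai(0, 10) == 0.0
    assert compute_esai(16, 5) == pytest.approx(3.2)  # reported as 320%
    assert compute_esai(7, 7) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        compute_esai(1, 0)


# ---------------------------------------------------------------- GSEA ES
def brute_force_es(metric, is_hit):
    """Independent step-through of the weighted KS running sum."""
    hits_total = sum(abs(m) for m, h in zip(metric, is_hit) if h)
    n_miss = sum(1 for h in is_hit if not h)
    running, best = 0.0, 0.0
    for m, h in zip(metric, is_hit):
        if h:
            running += abs(m) / hits_total
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


def test_enrichment_score_top_block_is_one():
    """Gene set occupying exactly the top of the ranking reaches ES = 1."""
    metric = np.linspace(10, 1, 10)
    hits = np.array([True] * 3 + [False] * 7)
    assert enrichment_score(metric, hits) == pytest.approx(1.0)


def test_enrichment_score_toy_oracle():
    """10-gene, 3-member ranking matches a brute-force running sum."""
    metric = np.array([10, 9, 8, 7, 6, 5, 4, 3, 2, 1], dtype=float)
    hits = np.zeros(10, dtype=bool)
    hits[[0, 3, 7]] = True
    es = enrichment_score(metric, hits)
    assert es == pytest.approx(brute_force_es(metric, hits), abs=1e-12)
    assert es == pytest.approx(0.85 - 2 / 7, abs=1e-12)


def test_enrichment_score_interleaved_is_near_zero():
    """Evenly interleaved hits with a flat metric give |ES| ~ 0; the
    permutation null is centred well below the planted-top value of 1."""
    rng = np.random.default_rng(0)
    M, n_hit = 200, 20
    metric = np.ones(M)
    hits = np.zeros(M, dtype=bool)
    hits[5::10] = True
    assert abs(enrichment_score(metric, hits)) < 0.05
    null = []
    for _ in range(300):
        h = np.zeros(M, dtype=bool)
        h[rng.choice(M, n_hit, replace=False)] = True
        null.append(abs(enrichment_score(metric, h)))
    assert np.mean(null) < 0.3


def test_enrichment_score_matches_oracle_on_random_rankings():
    rng = np.random.default_rng(3)
    for _ in range(20):
        metric = np.sort(rng.lognormal(0, 1, 50))[::-1]
        hits = np.zeros(50, dtype=bool)
        hits[rng.choice(50, 8, replace=False)] = True
        assert enrichment_score(metric, hits) == pytest.approx(
            brute_force_es(metric, hits), abs=1e-12
        )


def test_enrichment_score_rejects_degenerate_sets():
    with pytest.raises(ValueError):
        enrichment_score(np.ones(5), np.zeros(5, dtype=bool))
    with pytest.raises(ValueError):
        enrichment_score(np.ones(5), np.ones(5, dtype=bool))


# ---------------------------------------------------------------- embedding
def test_embed_duplicate_droplets_coincide(two_type):
    cells, _, sevs, _, _ = two_type
    doubled = DropletMatrix(
        sp.vstack([sevs.counts[:5], sevs.counts[:5]]),
        [f"x{i}" for i in range(10)],
        sevs.genes,
        "dup",
    )
    _, coords = embed_joint(cells, doubled, n_pcs=10)
    assert np.allclose(coords[:5], coords[5:], atol=1e-8)


def test_embed_separates_planted_types(two_type):
    from sklearn.metrics import silhouette_score

    cells, ann, _, _, _ = two_type
    coords, _ = embed_joint(cells, cells.subset_droplets(cells.barcodes[:1]), n_pcs=10)
    labels = ann.loc[cells.barcodes].to_numpy()
    assert silhouette_score(coords, labels) > 0


def test_embed_row_order_invariance(two_type):
    cells, _, sevs, _, _ = two_type
    perm = list(range(sevs.n_droplets))[::-1]
    sevs_perm = DropletMatrix(
        sevs.counts[perm], [sevs.barcodes[i] for i in perm], sevs.genes, "perm"
    )
    _, c1 = embed_joint(cells, sevs, n_pcs=10)
    _, c2 = embed_joint(cells, sevs_perm, n_pcs=10)
    assert np.allclose(np.abs(c1[perm]), np.abs(c2), atol=1e-6)


def test_embed_npcs_argument_error(two_type):
    cells, _, sevs, _, _ = two_type
    with pytest.raises(ValueError):
        embed_joint(cells, sevs, n_pcs=cells.n_genes + 1)


# ---------------------------------------------------------------- similarity
def test_similarity_single_type_takes_all_neighbors():
    rng = np.random.default_rng(0)
    cell_coords = rng.normal(size=(50, 3))
    ann = pd.Series("T", index=[f"c{i}" for i in range(50)])
    sim = similarity(rng.normal(size=(4, 3)), cell_coords, ann,
                     [f"c{i}" for i in range(50)], n_neighbors=10)
    assert (sim["T"] == 10).all()


def test_similarity_rows_sum_to_n_and_match_exhaustive_scan():
    """k-d-tree neighbor counts equal an all-pairs distance scan."""
    rng = np.random.default_rng(1)
    n_cells, n_sev, N = 200, 40, 10
    cell_coords = rng.normal(size=(n_cells, 5))
    sev_coords = rng.normal(size=(n_sev, 5))
    barcodes = [f"c{i}" for i in range(n_cells)]
    labels = rng.choice(["A", "B", "C"], size=n_cells)
    ann = pd.Series(labels, index=barcodes)
    sim = similarity(sev_coords, cell_coords, ann, barcodes, n_neighbors=N)
    assert (sim.sum(axis=1) == N).all()
    for i in range(n_sev):
        d = np.linalg.norm(cell_coords - sev_coords[i], axis=1)
        nearest = np.argsort(d)[:N]
        expected = pd.Series(labels[nearest]).value_counts()
        for t in sim.columns:
            assert sim.iloc[i][t] == expected.get(t, 0)


def test_similarity_requires_annotated_cells():
    with pytest.raises(ValueError, match="no annotated"):
        similarity(np.zeros((1, 2)), np.zeros((3, 2)),
                   pd.Series(dtype=str), ["a", "b", "c"], n_neighbors=1)


# ---------------------------------------------------------------- assignment
def test_assign_source_below_floor_is_unassigned():
    sim = pd.Series({"A": 1, "B": 1})
    bio = pd.Series({"A": 0.9, "B": -0.5})
    assert assign_source(sim, bio, min_similarity=2) is None


def test_assign_source_dominant_type():
    sim = pd.Series({"A": 10, "B": 0})
    bio = pd.Series({"A": 0.8, "B": 0.1})
    assert assign_source(sim, bio) == "A"


def test_assign_source_tie_prefers_larger_raw_similarity():
    # after min-max normalization both types combine to the same total
    sim = pd.Series({"A": 7, "B": 3})
    bio = pd.Series({"A": 0.0, "B": 1.0})
    assert assign_source(sim, bio) == "A"


def test_assign_source_lexical_tie_break():
    sim = pd.Series({"B": 5, "A": 5})
    bio = pd.Series({"B": 0.2, "A": 0.2})
    assert assign_source(sim, bio) == "A"


def test_assign_source_biogenesis_can_decide():
    """With similarity tied, the biogenesis term picks the source."""
    sim = pd.Series({"A": 5, "B": 5, "C": 0})
    bio = pd.Series({"A": 0.1, "B": 0.9, "C": 0.0})
    assert assign_source(sim, bio) == "B"


# ---------------------------------------------------------------- ESAI_c
def test_esai_c_no_sevs_is_zero():
    ann = pd.Series({"c1": "A", "c2": "B"})
    esai_c = compute_esai_c(pd.Series(dtype=object), ann)
    assert (esai_c == 0).all()


def test_esai_c_single_type_reduces_to_esai():
    ann = pd.Series({f"c{i}": "A" for i in range(10)})
    assignments = pd.Series({f"s{i}": "A" for i in range(4)})
    esai_c = compute_esai_c(assignments, ann)
    assert esai_c["A"] == pytest.approx(compute_esai(4, 10))


def test_deconvolve_two_type_recovery_and_conservation(two_type):
    """Planted 3:1 secretion is recovered; assignments are conserved."""
    cells, ann, sevs, truth, sev_go = two_type
    res = deconvolve(cells, sevs, ann, sev_go)
    assigned = res.assignments[res.assignments != UNASSIGNED]
    # conservation of droplets
    assert len(assigned) + res.n_unassigned == sevs.n_droplets
    # weighted identity: sum_ci ESAI_c * n_cells(ci) == #assigned
    n_cells = ann.value_counts().reindex(res.esai_c.index)
    assert (res.esai_c * n_cells).sum() == pytest.approx(len(assigned))
    # majority of sEVs trace back to their generating type
    accuracy = (assigned == truth.loc[assigned.index]).mean()
    assert accuracy > 0.9
    ratio = res.esai_c["A"] / res.esai_c["B"]
    assert 3.0 * 0.75 <= ratio <= 3.0 * 1.25


def test_deconvolve_min_similarity_monotone(two_type):
    """Raising the similarity floor never increases assigned droplets."""
    cells, ann, sevs, _, sev_go = two_type
    counts = []
    for floor in (0, 5, 9, 10):
        cfg = DeconvolutionConfig(min_similarity=floor)
        res = deconvolve(cells, sevs, ann, sev_go, cfg)
        counts.append(int((res.assignments != UNASSIGNED).sum()))
    assert counts == sorted(counts, reverse=True)


def test_deconvolve_empty_sev_set(two_type):
    cells, ann, sevs, _, sev_go = two_type
    empty = DropletMatrix(
        sp.csr_matrix((0, sevs.n_genes), dtype=int), [], sevs.genes, "none"
    )
    res = deconvolve(cells, empty, ann, sev_go)
    assert (res.esai_c == 0).all()
    assert res.esai == 0.0 and res.n_unassigned == 0


def test_biogenesis_scores_every_annotated_type(two_type):
    cells, ann, _, _, sev_go = two_type
    bio = biogenesis(cells, ann, sev_go)
    assert sorted(bio.index) == ["A", "B"]
    assert ((bio >= -1) & (bio <= 1)).all()


# ---------------------------------------------------------------- loaders
def test_load_annotation_round_trip(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text("barcode\tcell_type\nc1\tA\nc2\tB\n")
    ann = load_annotation(path)
    assert ann.to_dict() == {"c1": "A", "c2": "B"}


def test_load_annotation_duplicate_error(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text("c1\tA\nc1\tB\n")
    with pytest.raises(ValueError, match="duplicate"):
        load_annotation(path)


def test_load_gmt_and_bundled_set(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("S1\tdesc\tg1\tg2\tg3\nS2\tdesc\tg4\n")
    sets = load_gmt(path)
    assert sets["S1"] == ["g1", "g2", "g3"] and sets["S2"] == ["g4"]
    bundled = bundled_biogenesis_set()
    assert len(bundled) > 0 and len(set(bundled)) == len(bundled)
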