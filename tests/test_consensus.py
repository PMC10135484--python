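"""Rank rule, gene universe, NMF, consensus clustering, module cells."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from astromod import (
    CohortConfig,
    CountMatrix,
    EXCLUDED,
    ModuleDefinition,
    NormalizedMatrix,
    RankRule,
    SubmoduleLoading,
    assign_module_cells,
    build_gene_universe,
    consensus_cluster,
    define_modules,
    generate_cohort,
    nmf_factorize,
    run_cohort_nmf,
    select_rank,
)
from astromod.consensus import dendrogram_to_newick
from astromod.oracles import agglomerative_pearson, anls_nmf_loss


# --- select_rank -------------------------------------------------------

@pytest.mark.parametrize(
    "n,expected", [(0, EXCLUDED), (99, EXCLUDED), (100, 6), (200, 6),
                   (300, 6), (301, 8), (1000, 8)]
)
def test_rank_rule_boundaries(n, expected):
    assert select_rank(n) == expected


@given(st.integers(min_value=0, max_value=5000))
@settings(deadline=None)
def test_rank_rule_piecewise(n):
    expected = EXCLUDED if n < 100 else (6 if n <= 300 else 8)
    assert select_rank(n) == expected


def test_rank_rule_validation():
    with pytest.raises(ValueError):
        RankRule(rank_low=1)
    with pytest.raises(ValueError):
        RankRule(min_cells_exclude=400)


# --- build_gene_universe ----------------------------------------------

def markers_df(rows):
    return pd.DataFrame(rows, columns=["gene", "cluster", "log2fc", "p_adj"])


def test_universe_union_and_strict_inequality():
    mk = markers_df([
        ("gA", "C1", 1.0, 0.001),
        ("gA", "C2", 0.9, 0.001),   # shared gene appears once
        ("gB", "C1", 0.6, 0.001),   # exactly 0.6: excluded
        ("gC", "C2", 0.7, 0.2),     # not significant
        ("gD", "C2", 0.61, 0.01),
    ])
    assert build_gene_universe(mk) == ["gA", "gD"]


def test_universe_empty_raises():
    mk = markers_df([("gA", "C1", 0.1, 0.5)])
    with pytest.raises(ValueError, match="relax"):
        build_gene_universe(mk)


# --- nmf_factorize -----------------------------------------------------

def test_nmf_exact_rank_one():
    rng = np.random.default_rng(0)
    X = np.outer(rng.uniform(1, 2, 15), rng.uniform(1, 2, 12))
    W, H, losses = nmf_factorize(X, rank=1, max_iter=2000, tol=1e-12, seed=0)
    rel = np.linalg.norm(X - W @ H) / np.linalg.norm(X)
    assert rel < 1e-6


def test_nmf_loss_trace_non_increasing():
    rng = np.random.default_rng(1)
    X = rng.uniform(0, 1, size=(25, 18))
    _, _, losses = nmf_factorize(X, rank=4, seed=1)
    assert np.all(np.diff(losses) <= 1e-9)


def test_nmf_w_columns_unit_norm():
    rng = np.random.default_rng(2)
    X = rng.uniform(0, 1, size=(25, 18))
    W, H, _ = nmf_factorize(X, rank=3, seed=2)
    assert np.allclose(np.linalg.norm(W, axis=0), 1.0)


def test_nmf_deterministic_given_seed():
    rng = np.random.default_rng(3)
    X = rng.uniform(0, 1, size=(20, 15))
    W1, H1, _ = nmf_factorize(X, rank=3, seed=7)
    W2, H2, _ = nmf_factorize(X, rank=3, seed=7)
    assert np.array_equal(W1, W2) and np.array_equal(H1, H2)


def test_nmf_input_validation():
    X = np.ones((5, 4))
    with pytest.raises(ValueError, match="rank"):
        nmf_factorize(X, rank=4)
    X2 = X.copy(); X2[0, 0] = -1
    with pytest.raises(ValueError, match="nonnegative"):
        nmf_factorize(X2, rank=2)
    X3 = X.copy(); X3[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        nmf_factorize(X3, rank=2)


def test_nmf_matches_anls_oracle():
    rng = np.random.default_rng(4)
    X = rng.uniform(0, 1, size=(20, 30)) * rng.uniform(0.5, 2, size=(20, 1))
    _, _, losses = nmf_factorize(X, rank=3, seed=5)
    ref = anls_nmf_loss(X, rank=3, seed=6)
    assert abs(losses[-1] / ref - 1.0) < 0.05


# --- run_cohort_nmf ----------------------------------------------------

def tiny_cohort(sizes, n_genes=30, seed=0):
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"g{i:02d}" for i in range(n_genes)])
    samples = {}
    for i, n in enumerate(sizes):
        counts = rng.poisson(2.0, size=(n_genes, n))
        counts[0] += 1
        cells = pd.Index([f"s{i}_c{j}" for j in range(n)])
        samples[f"s{i}"] = CountMatrix(sp.csr_matrix(counts), genes, cells)
    return samples, list(genes)


def test_submodule_count_is_sum_of_ranks():
    samples, universe = tiny_cohort([150, 250, 400])
    subs = run_cohort_nmf(samples, universe, max_iter=30)
    assert len(subs) == 6 + 6 + 8
    assert all(s.gene_scores.shape == (30,) for s in subs)


def test_submodule_count_under_stricter_exclusion():
    samples, universe = tiny_cohort([150, 250, 400])
    rule = RankRule(min_cells_exclude=200)
    subs = run_cohort_nmf(samples, universe, rule=rule, max_iter=30)
    assert len(subs) == 6 + 8


def test_all_samples_excluded_raises():
    samples, universe = tiny_cohort([50, 60])
    with pytest.raises(ValueError, match="rank rule"):
        run_cohort_nmf(samples, universe)


# --- consensus_cluster -------------------------------------------------

def subs_from(vectors):
    return [SubmoduleLoading(f"s{i}", 0, np.asarray(v, float))
            for i, v in enumerate(vectors)]


def test_two_identical_groups_recovered():
    rng = np.random.default_rng(5)
    a = rng.uniform(0.1, 1, 20)
    b = rng.uniform(0.1, 1, 20)
    subs = subs_from([a, a, b, b, a])
    assignment, _ = consensus_cluster(subs, k=2)
    assert assignment[0] == assignment[1] == assignment[4]
    assert assignment[2] == assignment[3] != assignment[0]


def test_positive_scaling_keeps_assignment():
    rng = np.random.default_rng(6)
    vectors = [rng.uniform(0.1, 1, 15) for _ in range(6)]
    base, _ = consensus_cluster(subs_from(vectors), k=3)
    scaled = [v * s for v, s in zip(vectors, [1, 5, 0.2, 3, 10, 0.5])]
    new, _ = consensus_cluster(subs_from(scaled), k=3)
    assert np.array_equal(base, new)


def test_matches_textbook_agglomerative_oracle():
    rng = np.random.default_rng(7)
    templates = np.abs(rng.normal(size=(4, 25))) + 0.1
    vectors = [templates[g] + np.abs(rng.normal(scale=0.1, size=25))
               for g in range(4) for _ in range(3)]
    ours, _ = consensus_cluster(subs_from(vectors), k=4)
    ref = agglomerative_pearson(np.vstack(vectors), k=4)
    co_ours = ours[:, None] == ours[None, :]
    co_ref = ref[:, None] == ref[None, :]
    assert (co_ours == co_ref).all()


def test_input_order_invariance():
    rng = np.random.default_rng(8)
    templates = np.abs(rng.normal(size=(3, 20))) + 0.1
    vectors = [templates[g] + np.abs(rng.normal(scale=0.05, size=20))
               for g in range(3) for _ in range(4)]
    base, _ = consensus_cluster(subs_from(vectors), k=3)
    perm = rng.permutation(len(vectors))
    permuted, _ = consensus_cluster(subs_from([vectors[i] for i in perm]), k=3)
    co_a = base[perm][:, None] == base[perm][None, :]
    co_b = permuted[:, None] == permuted[None, :]
    assert (co_a == co_b).all()


def test_k_too_large_raises():
    with pytest.raises(ValueError, match="exceeds"):
        consensus_cluster(subs_from([[1, 2, 3], [3, 2, 1]]), k=5)


def test_newick_export_has_all_leaves():
    rng = np.random.default_rng(9)
    vectors = [rng.uniform(0.1, 1, 10) for _ in range(5)]
    _, Z = consensus_cluster(subs_from(vectors), k=2)
    nwk = dendrogram_to_newick(Z, [f"sub{i}" for i in range(5)])
    assert nwk.endswith(";")
    assert all(f"sub{i}" in nwk for i in range(5))


# --- define_modules ----------------------------------------------------

def test_single_member_cluster_keeps_its_top_genes():
    universe = [f"g{i}" for i in range(10)]
    v = np.arange(10, 0, -1, dtype=float)
    subs = subs_from([v, np.ones(10)])
    mods = define_modules(np.array([0, 1]), subs, universe, top_n=3)
    assert mods[0].genes == ["g0", "g1", "g2"]


def test_duplicate_members_are_idempotent():
    universe = [f"g{i}" for i in range(8)]
    rng = np.random.default_rng(10)
    v = rng.uniform(0.1, 1, 8)
    one = define_modules(np.array([0]), subs_from([v]), universe, top_n=4)
    two = define_modules(np.array([0, 0]), subs_from([v, v]), universe, top_n=4)
    assert one[0].genes == two[0].genes


# --- assign_module_cells -----------------------------------------------

def module_cell_norm(n_expressed):
    """One cell expressing n_expressed of 20 module genes."""
    mat = np.zeros((20, 1))
    mat[:n_expressed, 0] = 1.0
    genes = pd.Index([f"g{i:02d}" for i in range(20)])
    return NormalizedMatrix(sp.csr_matrix(mat), genes, pd.Index(["c0"]))


@pytest.mark.parametrize("n_expressed,is_module_cell", [(14, True), (13, False)])
def test_seventy_percent_boundary(n_expressed, is_module_cell):
    """ceil(0.7 * 20) = 14 expressed genes is the module-cell threshold."""
    norm = module_cell_norm(n_expressed)
    mod = ModuleDefinition("M1", [f"g{i:02d}" for i in range(20)])
    calls = assign_module_cells(norm, [mod], 0.7)
    assert bool(calls.loc["c0", "M1"]) is is_module_cell


def test_counts_monotone_in_threshold(canonical, canonical_norm):
    _, _, _, truth = canonical
    mods = [ModuleDefinition(p, truth.program_top_genes(p, 20))
            for p in truth.program_genes]
    counts = [assign_module_cells(canonical_norm, mods, t).to_numpy().sum()
              for t in (0.5, 0.6, 0.7, 0.8, 0.9)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_assignment_invariant_to_positive_rescaling(canonical_norm):
    sub = canonical_norm.subset_cells(canonical_norm.cells[:100])
    mod = ModuleDefinition("M1", list(sub.genes[:20]))
    base = assign_module_cells(sub, [mod], 0.7)
    scaled = NormalizedMatrix(sub.values * 3.7, sub.genes, sub.cells)
    assert base.equals(assign_module_cells(scaled, [mod], 0.7))


def test_threshold_validation(canonical_norm):
    mod = ModuleDefinition("M1", list(canonical_norm.genes[:20]))
    with pytest.raises(ValueError):
        assign_module_cells(canonical_norm, [mod], 0.0)
    with pytest.raises(ValueError):
        assign_module_cells(canonical_norm, [mod], 1.5)
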