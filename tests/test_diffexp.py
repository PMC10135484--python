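"""Region-matched DE, set logic, PCA, module tests, dependency."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from astromod import (
    CohortConfig,
    Contrast,
    GeneSignature,
    contrasts_from_metadata,
    disorder_pca,
    generate_cohort,
    lognormalize,
    module_dependency,
    module_group_test,
    region_matched_deg,
    score_signature,
    shared_deg_sets,
)
from astromod.oracles import subset_decomposition
from astromod.pipeline import pool_samples


@pytest.fixture(scope="module")
def de_cohort():
    """Single-region cohort with five 4-fold disease genes planted on
    moderately expressed background genes."""
    base_cfg = CohortConfig(
        n_samples=4, cells_per_sample=(100, 120), n_genes=300,
        n_programs=2, program_size=50, region_labels={"CTX": 1.0}, seed=77,
    )
    _, _, probe = generate_cohort(base_cfg)
    prog = {g for gl in probe.program_genes.values() for g in gl}
    bm = probe.base_means
    target = list(bm[(bm > 0.4) & (bm < 1.0)].index.difference(prog)[:5])
    cfg = CohortConfig(
        n_samples=4, cells_per_sample=(100, 120), n_genes=300,
        n_programs=2, program_size=50, region_labels={"CTX": 1.0},
        disorder_effects={"AD": (target, 4.0)}, seed=77,
    )
    samples, meta, truth = generate_cohort(cfg)
    norm = lognormalize(pool_samples(samples))
    return samples, meta, truth, norm, target


def test_planted_fold_change_detected(de_cohort):
    _, meta, truth, norm, target = de_cohort
    degs = region_matched_deg(norm, truth.sample_of_cell,
                              contrasts_from_metadata(meta))
    table = degs[("AD", "CTX")].set_index("gene")
    assert all(table.loc[g, "direction"] == "up" for g in target)


def test_swapping_sides_maps_up_to_down(de_cohort):
    _, meta, truth, norm, target = de_cohort
    fwd = contrasts_from_metadata(meta)[0]
    rev = Contrast("AD", "CTX", fwd.control_samples, fwd.case_samples)
    d_fwd = region_matched_deg(norm, truth.sample_of_cell, [fwd])[("AD", "CTX")]
    d_rev = region_matched_deg(norm, truth.sample_of_cell, [rev])[("AD", "CTX")]
    up_fwd = set(d_fwd[d_fwd.direction == "up"]["gene"])
    down_rev = set(d_rev[d_rev.direction == "down"]["gene"])
    assert up_fwd == down_rev


def test_missing_control_contrast_skipped(de_cohort):
    _, meta, truth, norm, _ = de_cohort
    ct = Contrast("AD", "CTX", ["S01"], ["S02"])
    bad = Contrast("AD", "HIP", ["nope1"], ["nope2"])
    degs = region_matched_deg(norm, truth.sample_of_cell, [ct, bad])
    assert ("AD", "HIP") not in degs


# --- shared_deg_sets ---------------------------------------------------

def test_shared_sets_direct_example():
    sets = {"A": ["g1", "g2"], "B": ["g1"], "C": ["g1", "g3"]}
    shared, table = shared_deg_sets(sets, min_disorders=3)
    assert shared == ["g1"]
    assert table["count"].sum() == 3  # |union|


def test_disjoint_sets():
    sets = {"A": ["g1"], "B": ["g2"], "C": ["g3", "g4"]}
    shared, table = shared_deg_sets(sets, min_disorders=3)
    assert shared == []
    assert dict(zip(table["combination"], table["count"])) == {
        "A": 1, "B": 1, "C": 2
    }


@given(st.integers(min_value=0, max_value=10_000))
@settings(deadline=None, max_examples=20)
def test_shared_sets_match_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(100)]
    sets = {f"D{k}": [g for g in genes if rng.random() < 0.3]
            for k in range(4)}
    sets = {k: v for k, v in sets.items() if True}
    shared, table = shared_deg_sets(sets, min_disorders=2)
    ref = subset_decomposition(sets)
    got = {frozenset(r["combination"].split("&")): r["count"]
           for _, r in table.iterrows()}
    assert got == ref
    ref_shared = sorted(g for g in genes
                        if sum(g in set(v) for v in sets.values()) >= 2)
    assert shared == ref_shared


# --- disorder_pca ------------------------------------------------------

@pytest.fixture(scope="module")
def pca_setup():
    genes_a = [f"G{i:05d}" for i in range(900, 950)]
    genes_b = [f"G{i:05d}" for i in range(950, 1000)]
    cfg = CohortConfig(
        n_samples=16, cells_per_sample=(150, 250), seed=21,
        region_labels={"CTX": 0.5, "BG": 0.5},
        disorder_effects={"AD": (genes_a + genes_b, 1.5)},
        region_effects={"CTX": (genes_a, 4.0), "BG": (genes_b, 4.0)},
    )
    samples, meta, truth = generate_cohort(cfg)
    norm = lognormalize(pool_samples(samples))
    degs = region_matched_deg(norm, truth.sample_of_cell,
                              contrasts_from_metadata(meta))
    tables = {f"{d}_{r}": t for (d, r), t in degs.items()}
    groups = {}
    for sid, d, r in meta[["sample_id", "disorder", "region"]].itertuples(
            index=False):
        groups[f"{d}|{r}|{sid}"] = list(samples[sid].cells)
    return norm, tables, groups


def test_pca_explained_variance_properties(pca_setup):
    norm, tables, groups = pca_setup
    coords, evr = disorder_pca(norm, tables, groups)
    assert coords.shape == (len(groups), 3)
    assert np.all(np.diff(evr) <= 1e-12)
    assert evr.sum() <= 1.0 + 1e-9


def test_pca_duplicated_group_identical_coordinates(pca_setup):
    norm, tables, groups = pca_setup
    g2 = dict(groups)
    first = next(iter(groups))
    g2["copy"] = list(groups[first])
    coords, _ = disorder_pca(norm, tables, g2)
    assert np.allclose(coords.loc[first], coords.loc["copy"], atol=1e-9)


def test_pca_separates_regions(pca_setup):
    from sklearn.metrics import silhouette_score
    norm, tables, groups = pca_setup
    coords, _ = disorder_pca(norm, tables, groups)
    regions = [g.split("|")[1] for g in coords.index]
    assert silhouette_score(coords.to_numpy(), regions) > 0.5


def test_pca_needs_enough_groups(pca_setup):
    norm, tables, groups = pca_setup
    few = dict(list(groups.items())[:3])
    with pytest.raises(ValueError, match="4 sample groups"):
        disorder_pca(norm, tables, few)


# --- module_group_test -------------------------------------------------

def test_identical_distributions_give_p_one():
    scores = pd.DataFrame({"M1": np.tile([1.0, 2.0, 3.0], 4)},
                          index=[f"c{i}" for i in range(12)])
    meta = pd.DataFrame({"sample": ["a"] * 6 + ["b"] * 6}, index=scores.index)
    ct = Contrast("X", "CTX", ["a"], ["b"])
    res = module_group_test(scores, meta, [ct])
    assert res["p"].iloc[0] > 0.9


def test_fully_separated_three_vs_three_exact_p():
    scores = pd.DataFrame({"M1": [10.0, 11, 12, 1, 2, 3]},
                          index=[f"c{i}" for i in range(6)])
    meta = pd.DataFrame({"sample": ["a"] * 3 + ["b"] * 3}, index=scores.index)
    res = module_group_test(scores, meta, [Contrast("X", "CTX", ["a"], ["b"])])
    assert res["p"].iloc[0] == pytest.approx(0.1)
    assert res["direction"].iloc[0] == "up"


def test_planted_disorder_shift_flags_only_that_module():
    """An activity boost of one program in disease samples is detected
    (p < 0.01, up) while the other programs stay below detection."""
    detected = only = 0
    reps = 10
    for rep in range(reps):
        cfg = CohortConfig(
            n_samples=6, cells_per_sample=(150, 250), n_genes=2000,
            program_size=20, region_labels={"CTX": 1.0}, batch_sd=0.0,
            program_activity_fraction=0.2,
            program_activity_by_disorder={"P2": {"AD": 0.55, "Control": 0.2}},
            seed=7000 + rep,
        )
        samples, meta, truth = generate_cohort(cfg)
        norm = lognormalize(pool_samples(samples))
        sigs = [GeneSignature(p, truth.program_genes[p])
                for p in truth.program_genes]
        sc = score_signature(norm, sigs, seed=rep, exclude_query_genes=True)
        cmeta = pd.DataFrame({"sample": truth.sample_of_cell})
        res = module_group_test(sc, cmeta,
                                contrasts_from_metadata(meta)).set_index("module")
        d = res.loc["P2", "p"] < 0.01 and res.loc["P2", "direction"] == "up"
        detected += d
        only += d and all(res.loc[m, "p"] >= 0.01 for m in ["P1", "P3", "P4"])
    assert detected / reps >= 0.9
    assert only / reps >= 0.8


# --- module_dependency -------------------------------------------------

def test_duplicate_module_is_co_occurrent():
    rng = np.random.default_rng(1)
    s = rng.normal(size=50)
    scores = pd.DataFrame({"A": s, "B": s + 0.0})
    dep = module_dependency(scores)
    assert dep.r.loc["A", "B"] == pytest.approx(1.0)
    assert dep.classification.loc["A", "B"] == "co-occurrent"


def test_rank_invariance_under_monotone_transform():
    rng = np.random.default_rng(2)
    scores = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("ABC"))
    transformed = scores.copy()
    transformed["B"] = np.exp(transformed["B"])
    a = module_dependency(scores)
    b = module_dependency(transformed)
    assert np.allclose(a.r.to_numpy(), b.r.to_numpy(), atol=1e-12)


def test_dependency_symmetry_and_diagonal():
    rng = np.random.default_rng(3)
    scores = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("ABCD"))
    dep = module_dependency(scores)
    assert np.allclose(dep.r.to_numpy(), dep.r.to_numpy().T)
    assert np.allclose(np.diag(dep.r.to_numpy()), 1.0)
    assert (dep.classification.to_numpy() == dep.classification.to_numpy().T).all()


def test_constant_column_flagged_undefined():
    rng = np.random.default_rng(4)
    scores = pd.DataFrame({"A": rng.normal(size=20), "B": np.zeros(20)})
    dep = module_dependency(scores)
    assert dep.classification.loc["A", "B"] == "undefined"
    assert np.isnan(dep.r.loc["A", "B"])


def test_too_few_cells_raises():
    scores = pd.DataFrame({"A": np.arange(5.0), "B": np.arange(5.0)})
    with pytest.raises(ValueError, match="10 cells"):
        module_dependency(scores)
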