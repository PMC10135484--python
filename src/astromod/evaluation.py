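"""Self-contained evaluation experiments on the synthetic cohort.

Each function generates its inputs with the package's own generator,
runs the method under study, and measures recovery, calibration or
oracle agreement. They are used by the test suite and by the
reproduction script; all randomness derives from the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import oracles
from .consensus import ModuleDefinition, assign_module_cells, nmf_factorize, select_rank
from .diffexp import (
    contrasts_from_metadata,
    module_dependency,
    module_group_test,
    region_matched_deg,
    shared_deg_sets,
)
from .pipeline import discover_modules, match_modules_to_programs, pool_samples
from .preprocess import lognormalize
from .proteomics import (
    match_module_proteins,
    module_trait_analysis,
    protein_module_score,
)
from .scoring import GeneSignature, score_signature
from .stats import rank_sum_p
from .syndata import CohortConfig, generate_cohort, generate_proteome


def canonical_config(seed: int) -> CohortConfig:
    """The canonical desk-scale cohort: 12 samples, 150-400 cells, 1,000
    genes, 4 disjoint 50-gene programs, 6-fold program effect."""
    return CohortConfig(seed=seed)


def rank_rule_accuracy(n_max: int = 1000) -> dict:
    """Fraction of cell counts 0..n_max mapped per the stated rule."""
    correct = 0
    for n in range(n_max + 1):
        expected = None if n < 100 else (6 if n <= 300 else 8)
        if select_rank(n) == expected:
            correct += 1
    return {"value": correct / (n_max + 1), "n": n_max + 1}


def planted_recovery(seed: int, n_seeds: int = 5) -> dict:
    """Mean top-20 Jaccard of discovered vs planted programs, over
    independently generated cohorts and NMF initializations."""
    per_seed = []
    for i in range(n_seeds):
        cfg = canonical_config(seed + i)
        samples, _, truth = generate_cohort(cfg)
        res = discover_modules(
            samples, truth.cluster_of_cell, k=cfg.n_programs, seed=seed + 1000 + i
        )
        planted = {p: truth.program_top_genes(p, 20) for p in truth.program_genes}
        jac = match_modules_to_programs(res.modules, planted)
        per_seed.append(float(np.mean(list(jac.values()))))
    return {"value": float(np.mean(per_seed)), "per_seed": per_seed, "n": n_seeds}


def module_cell_rule(seed: int) -> dict:
    """Sensitivity/specificity of the >=70%-expressed rule against planted
    program activity, plus module-cell counts over a threshold sweep."""
    cfg = canonical_config(seed)
    samples, _, truth = generate_cohort(cfg)
    norm = lognormalize(pool_samples(samples))
    mods = [
        ModuleDefinition(module_id=p, genes=truth.program_top_genes(p, 20))
        for p in truth.program_genes
    ]
    calls = assign_module_cells(norm, mods, 0.7)
    sens, spec = [], []
    for p in truth.program_genes:
        actual = truth.program_active[p].to_numpy()
        pred = calls[p].to_numpy()
        sens.append((pred & actual).sum() / actual.sum())
        spec.append((~pred & ~actual).sum() / (~actual).sum())
    thresholds = (0.5, 0.6, 0.7, 0.8, 0.9)
    counts = [
        int(assign_module_cells(norm, mods, t).to_numpy().sum()) for t in thresholds
    ]
    return {
        "sensitivity": float(min(sens)),
        "specificity": float(min(spec)),
        "counts_by_threshold": counts,
        "monotone": all(a >= b for a, b in zip(counts, counts[1:])),
        "n": int(norm.n_cells),
    }


def wilcoxon_exact_deviation(seed: int, reps_per_pair: int = 3) -> dict:
    """Max |p - exact permutation p| over all group-size pairs 3..8 with
    continuous (untied) data."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    n_checked = 0
    for n in range(3, 9):
        for m in range(n, 9):
            for _ in range(reps_per_pair):
                x = rng.normal(size=n)
                y = rng.normal(loc=rng.uniform(-2, 2), size=m)
                p = float(rank_sum_p(x, y))
                p_exact = oracles.exact_rank_sum_p(x, y)
                worst = max(worst, abs(p - p_exact))
                n_checked += 1
    return {"value": worst, "n": n_checked}


def consensus_oracle_agreement(seed: int, n_groups: int = 4,
                               per_group: int = 3) -> dict:
    """Partition agreement of the clustering path vs the brute-force
    agglomerative oracle on structured random submodules."""
    from .consensus import SubmoduleLoading, consensus_cluster

    rng = np.random.default_rng(seed)
    templates = np.abs(rng.normal(size=(n_groups, 30))) + 0.1
    vectors, subs = [], []
    for g in range(n_groups):
        for r in range(per_group):
            v = templates[g] + np.abs(rng.normal(scale=0.1, size=30))
            vectors.append(v)
            subs.append(SubmoduleLoading(f"S{g}{r}", r, v))
    vectors = np.vstack(vectors)
    ours, _ = consensus_cluster(subs, k=n_groups, linkage="average")
    ref = oracles.agglomerative_pearson(vectors, k=n_groups, linkage="average")
    same = (ours[:, None] == ours[None, :])
    same_ref = (ref[:, None] == ref[None, :])
    return {"value": float((same == same_ref).all()), "n": len(subs)}


def shared_sets_oracle_agreement(seed: int, n_sets: int = 6,
                                 n_genes: int = 500) -> dict:
    """Exact agreement of the UpSet combination table with exhaustive
    subset enumeration on random gene sets."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    sets = {
        f"D{k}": [g for g in genes if rng.random() < 0.3] for k in range(n_sets)
    }
    shared, table = shared_deg_sets(sets, min_disorders=3)
    ref = oracles.subset_decomposition(sets)
    got = {
        frozenset(row["combination"].split("&")): row["count"]
        for _, row in table.iterrows()
    }
    counts_match = got == ref
    ref_shared = sorted(
        g for g in genes
        if sum(g in s for s in sets.values()) >= 3
    )
    return {"value": float(counts_match and shared == ref_shared), "n": n_sets}


def nmf_anls_ratio(seed: int) -> dict:
    """Final MU-NMF loss relative to a multi-restart ANLS oracle on a
    random 20 x 30 instance at rank 3."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, size=(20, 30)) * rng.uniform(0.5, 2.0, size=(20, 1))
    _, _, losses = nmf_factorize(X, rank=3, seed=seed + 1)
    ref = oracles.anls_nmf_loss(X, rank=3, seed=seed + 2)
    return {"value": float(losses[-1] / ref), "n": X.size}


def null_signature_bias(seed: int, n_signatures: int = 100) -> dict:
    """Mean |mean cell score| of random 20-gene signatures on the
    canonical cohort (null calibration of the binned-control scorer)."""
    cfg = canonical_config(seed)
    samples, _, _ = generate_cohort(cfg)
    norm = lognormalize(pool_samples(samples))
    rng = np.random.default_rng(seed + 1)
    sigs = [
        GeneSignature(
            f"rand{i}", list(rng.choice(norm.genes, size=20, replace=False))
        )
        for i in range(n_signatures)
    ]
    scores = score_signature(norm, sigs, seed=seed + 2)
    return {
        "value": float(scores.mean(axis=0).abs().mean()),
        "n": n_signatures,
    }


def _null_cohort(seed: int) -> tuple:
    cfg = CohortConfig(
        n_samples=4,
        cells_per_sample=(100, 120),
        n_genes=300,
        n_programs=2,
        program_size=50,
        region_labels={"CTX": 1.0},
        seed=seed,
    )
    samples, meta, truth = generate_cohort(cfg)
    norm = lognormalize(pool_samples(samples))
    return samples, meta, truth, norm


def null_deg_fwer(seed: int, n_reps: int = 50) -> dict:
    """Family-wise rejection rate of region-matched DE under global
    cell-label permutation (exchangeable null)."""
    _, meta, truth, norm = _null_cohort(seed)
    contrasts = contrasts_from_metadata(meta)
    rng = np.random.default_rng(seed + 1)
    hits = 0
    for _ in range(n_reps):
        perm = pd.Series(
            rng.permutation(truth.sample_of_cell.to_numpy()), index=norm.cells
        )
        degs = region_matched_deg(norm, perm, contrasts)
        any_sig = any((t["direction"] != "ns").any() for t in degs.values())
        hits += any_sig
    return {"value": hits / n_reps, "n": n_reps}


def null_module_test_rate(seed: int, n_reps: int = 50) -> dict:
    """Per-test rejection rate (p < 0.05) of module score group tests
    under global cell-label permutation."""
    _, meta, truth, norm = _null_cohort(seed)
    contrasts = contrasts_from_metadata(meta)
    sigs = [
        GeneSignature(p, truth.program_top_genes(p, 20))
        for p in truth.program_genes
    ]
    scores = score_signature(norm, sigs, seed=seed + 2)
    rng = np.random.default_rng(seed + 3)
    ps = []
    for _ in range(n_reps):
        perm = pd.DataFrame(
            {"sample": rng.permutation(truth.sample_of_cell.to_numpy())},
            index=norm.cells,
        )
        res = module_group_test(scores, perm, contrasts)
        ps.extend(res["p"].tolist())
    ps = np.asarray(ps)
    return {"value": float((ps < 0.05).mean()), "n": len(ps)}


def null_trait_fp_rate(seed: int, n_reps: int = 200) -> dict:
    """False-positive rate of module-trait Spearman correlations when
    traits are independent of all modules."""
    modules = {f"M{i}": [f"M{i}_g{j}" for j in range(10)] for i in range(1, 5)}
    hits = total = 0
    for rep in range(n_reps):
        ab, tr = generate_proteome(
            modules,
            {"control": 20, "AsymAD": 20, "AD": 20},
            within_module_r=0.6,
            seed=seed + rep,
        )
        matches = match_module_proteins(modules, ab)
        scores = protein_module_score(ab, matches)
        res = module_trait_analysis(scores, tr)
        p = res.trait_p.to_numpy().ravel()
        hits += int((p < 0.05).sum())
        total += p.size
    return {"value": hits / total, "n": total}


def dependency_recovery(seed: int, n_reps: int = 50) -> dict:
    """Recovery of planted co-occurring and mutually exclusive program
    pairs by the Spearman +-0.3 classification."""
    co = ex = 0
    for rep in range(n_reps):
        cfg = CohortConfig(
            n_samples=2,
            cells_per_sample=(350, 400),
            n_genes=300,
            n_programs=4,
            program_size=50,
            program_home_weight=1.0,
            coactive_pairs=[(0, 1)],
            exclusive_pairs=[(2, 3)],
            seed=seed + rep,
        )
        samples, _, truth = generate_cohort(cfg)
        norm = lognormalize(pool_samples(samples))
        sigs = [
            GeneSignature(p, truth.program_top_genes(p, 20))
            for p in truth.program_genes
        ]
        scores = score_signature(norm, sigs, seed=seed + rep)
        dep = module_dependency(scores)
        co += dep.classification.loc["P1", "P2"] == "co-occurrent"
        ex += dep.classification.loc["P3", "P4"] == "exclusive"
    return {"cooccur_rate": co / n_reps, "exclusive_rate": ex / n_reps,
            "n": n_reps}


def proteomic_shift_detection(seed: int, n_reps: int = 50) -> dict:
    """Detection of a planted early-stage (AsymAD) module shift: the
    shifted module's control-vs-AsymAD Wilcoxon p < 0.01 while no other
    module crosses that detection threshold."""
    modules = {f"M{i}": [f"M{i}_g{j}" for j in range(20)] for i in range(1, 5)}
    hits = 0
    for rep in range(n_reps):
        ab, tr = generate_proteome(
            modules,
            {"control": 30, "AsymAD": 30, "AD": 30},
            within_module_r=0.6,
            status_shifts={"M2": {"AsymAD": 1.5, "AD": 1.5}},
            seed=seed + rep,
        )
        matches = match_module_proteins(modules, ab)
        scores = protein_module_score(ab, matches)
        res = module_trait_analysis(scores, tr)
        st = res.status_tests
        sub = st[(st.status_a == "control") & (st.status_b == "AsymAD")]
        sub = sub.set_index("module")
        detected = sub.loc["M2", "p"] < 0.01 and sub.loc["M2", "median_diff"] < 0
        others = all(sub.loc[m, "p"] >= 0.01 for m in ["M1", "M3", "M4"])
        hits += detected and others
    return {"value": hits / n_reps, "n": n_reps}
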