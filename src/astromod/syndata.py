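"""Synthetic multi-sample single-cell cohorts with planted structure.

The generator emulates the statistical structure the downstream analysis
assumes: negative-binomial UMI counts (gamma-Poisson mixture), planted cell
subtypes, planted co-expression programs active in a subset of cells,
per-sample multiplicative batch effects, per-cell library-size variation,
and per-sample region/disorder labels. A companion spatial spot grid and a
module-correlated proteome with simulated neuropathology traits are
generated with the same count model.

Cell subtypes are defined by program preference: each program has a "home"
subtype in which it is preferentially active, so subtype markers are (by
default) the home program's genes. Constitutive subtype markers can be
planted in addition via ``cluster_marker_size``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix

#: continuous trait columns of the synthetic proteome (plaque burden,
#: tangle burden, cognition, and three MS-style molecular measurements)
TRAIT_NAMES = ("plaque", "tangle", "cognition", "abeta", "tau", "asyn")


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults are the canonical desk-scale cohort used throughout the test
    suite: 12 samples of 150-400 cells, 1,000 genes, 4 disjoint 50-gene
    programs active in 35% of cells with a 6-fold multiplicative effect.
    """

    n_samples: int = 12
    cells_per_sample: tuple[int, int] = (150, 400)
    n_genes: int = 1000
    n_clusters: int = 4
    n_programs: int = 4
    program_size: int = 50
    program_activity_fraction: float = 0.35
    effect_size: float = 6.0
    batch_sd: float = 0.15
    nb_dispersion: float = 2.0
    library_sd: float = 0.3
    base_mean_scale: float = 1.0
    program_home_weight: float = 4.0
    cluster_marker_size: int = 0
    cluster_marker_fold: float = 4.0
    region_labels: Mapping[str, float] = field(
        default_factory=lambda: {"CTX": 0.5, "BG": 0.5}
    )
    disorder_labels: Mapping[str, float] = field(
        default_factory=lambda: {"Control": 0.5, "AD": 0.5}
    )
    program_activity_by_disorder: Mapping[str, Mapping[str, float]] | None = None
    coactive_pairs: Sequence[tuple[int, int]] = ()
    exclusive_pairs: Sequence[tuple[int, int]] = ()
    disorder_effects: Mapping[str, tuple[Sequence[str], float]] | None = None
    region_effects: Mapping[str, tuple[Sequence[str], float]] | None = None
    balanced_labels: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < self.n_programs * self.program_size + \
                self.n_clusters * self.cluster_marker_size:
            raise ValueError(
                "n_genes too small for the requested disjoint program and "
                "marker gene sets"
            )
        if self.n_programs < 2:
            raise ValueError("n_programs must be >= 2")
        if self.program_size < 20:
            raise ValueError("program_size must be >= 20")
        if not 0.0 <= self.program_activity_fraction <= 1.0:
            raise ValueError("program_activity_fraction must lie in [0, 1]")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not self.region_labels or not self.disorder_labels:
            raise ValueError("region and disorder label sets must be non-empty")
        for i, j in list(self.coactive_pairs) + list(self.exclusive_pairs):
            if not (0 <= i < j < self.n_programs):
                raise ValueError(f"invalid program pair ({i}, {j})")


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort."""

    program_genes: dict[str, list[str]]
    program_active: pd.DataFrame  # cells x programs, bool
    cluster_of_cell: pd.Series
    sample_of_cell: pd.Series
    cluster_markers: dict[str, list[str]]
    program_home_cluster: dict[str, str]
    base_means: pd.Series

    def program_top_genes(self, program_id: str, n: int = 20) -> list[str]:
        """Top-n genes of a planted program by expected baseline expression."""
        genes = self.program_genes[program_id]
        means = self.base_means.loc[genes]
        order = sorted(genes, key=lambda g: (-means[g], g))
        return order[:n]


def _gene_ids(n: int) -> pd.Index:
    width = max(5, len(str(n)))
    return pd.Index([f"G{i:0{width}d}" for i in range(n)])


def _weighted_sample(rng, candidates: np.ndarray, weights: np.ndarray,
                     n: int) -> np.ndarray:
    """Sample n indices without replacement with probability ~ weights."""
    if n <= 0:
        return np.empty(0, dtype=int)
    w = weights.astype(float)
    total = w.sum()
    if n > (w > 0).sum():
        raise ValueError("not enough candidate cells for requested activity")
    return rng.choice(candidates, size=n, replace=False, p=w / total)


def generate_cohort(
    config: CohortConfig,
) -> tuple[dict[str, CountMatrix], pd.DataFrame, GroundTruth]:
    """Generate one synthetic cohort.

    Returns one count matrix per sample (genes x cells), a sample metadata
    table (sample_id, disorder, region, platform), and the planted ground
    truth. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)

    # --- planted gene sets (disjoint by construction)
    perm = rng.permutation(config.n_genes)
    program_rows = {
        f"P{p + 1}": perm[p * config.program_size:(p + 1) * config.program_size]
        for p in range(config.n_programs)
    }
    offset = config.n_programs * config.program_size
    marker_rows = {}
    for c in range(config.n_clusters):
        lo = offset + c * config.cluster_marker_size
        marker_rows[f"C{c + 1}"] = perm[lo:lo + config.cluster_marker_size]

    # --- baseline per-gene means; program genes sit in a narrower, slightly
    # higher band so the >0-expression module-cell rule has a stable footing
    base = rng.lognormal(math.log(0.2), 1.0, size=config.n_genes)
    for rows in program_rows.values():
        base[rows] = rng.lognormal(math.log(0.5), 0.3, size=len(rows))
    for rows in marker_rows.values():
        if len(rows):
            base[rows] = rng.lognormal(math.log(0.4), 0.4, size=len(rows))
    base *= config.base_mean_scale

    # --- sample frame
    lo, hi = config.cells_per_sample
    sizes = rng.integers(lo, hi + 1, size=config.n_samples)
    regions = list(config.region_labels)
    region_p = np.array(list(config.region_labels.values()), dtype=float)
    disorders = list(config.disorder_labels)
    disorder_p = np.array(list(config.disorder_labels.values()), dtype=float)
    sample_ids = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    if config.balanced_labels:
        # cycle over the disorder x region product so every contrast has
        # samples on both sides even in small cohorts
        pairs = [(d, r) for r in regions for d in disorders]
        assigned = [pairs[i % len(pairs)] for i in range(config.n_samples)]
        disorder_col = [d for d, _ in assigned]
        region_col = [r for _, r in assigned]
    else:
        disorder_col = rng.choice(
            disorders, size=config.n_samples, p=_normalize_probs(disorder_p)
        )
        region_col = rng.choice(
            regions, size=config.n_samples, p=_normalize_probs(region_p)
        )
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "disorder": disorder_col,
            "region": region_col,
            "platform": "synthetic-10x",
            "n_cells": sizes,
        }
    )

    # --- cells
    cell_ids, cell_sample, cell_cluster = [], [], []
    for sid, n in zip(sample_ids, sizes):
        cell_ids += [f"{sid}_c{i:04d}" for i in range(n)]
        cell_sample += [sid] * n
        cell_cluster += list(rng.integers(0, config.n_clusters, size=n))
    cell_ids = pd.Index(cell_ids)
    cell_sample = pd.Series(cell_sample, index=cell_ids, name="sample")
    cluster_arr = np.asarray(cell_cluster)
    cell_cluster = pd.Series(
        [f"C{c + 1}" for c in cluster_arr], index=cell_ids, name="cluster"
    )
    n_cells_total = len(cell_ids)
    cell_disorder = cell_sample.map(metadata.set_index("sample_id")["disorder"])

    # --- planted program activity with home-subtype preference
    home = {f"P{p + 1}": p % config.n_clusters for p in range(config.n_programs)}
    coactive = {j: i for i, j in config.coactive_pairs}
    exclusive = {j: i for i, j in config.exclusive_pairs}
    active = np.zeros((n_cells_total, config.n_programs), dtype=bool)
    overrides = config.program_activity_by_disorder or {}
    for p in range(config.n_programs):
        pid = f"P{p + 1}"
        if p in coactive:
            active[:, p] = active[:, coactive[p]]
            continue
        weights = np.where(
            cluster_arr == home[pid], config.program_home_weight, 1.0
        )
        if p in exclusive:
            weights = weights * (~active[:, exclusive[p]])
        frac_by_disorder = overrides.get(pid, {})
        if frac_by_disorder:
            for d in disorders:
                frac = frac_by_disorder.get(d, config.program_activity_fraction)
                in_d = (cell_disorder == d).to_numpy()
                n_active = round(frac * in_d.sum())
                idx = _weighted_sample(
                    rng, np.flatnonzero(in_d), weights[in_d], n_active
                )
                active[idx, p] = True
        else:
            n_active = round(config.program_activity_fraction * n_cells_total)
            idx = _weighted_sample(
                rng, np.arange(n_cells_total), weights, n_active
            )
            active[idx, p] = True
    program_active = pd.DataFrame(
        active, index=cell_ids, columns=list(program_rows)
    )

    # --- per-sample counts
    theta = config.nb_dispersion
    samples: dict[str, CountMatrix] = {}
    start = 0
    meta_idx = metadata.set_index("sample_id")
    for sid, n in zip(sample_ids, sizes):
        sl = slice(start, start + n)
        start += n
        batch = np.exp(rng.normal(0.0, config.batch_sd, size=config.n_genes))
        lib = np.exp(rng.normal(0.0, config.library_sd, size=n))
        mu = np.outer(base * batch, lib)
        for pid, rows in program_rows.items():
            act = active[sl, list(program_rows).index(pid)]
            if act.any():
                mu[np.ix_(rows, act)] *= config.effect_size
        for cid, rows in marker_rows.items():
            if len(rows):
                in_c = (cell_cluster.iloc[sl] == cid).to_numpy()
                if in_c.any():
                    mu[np.ix_(rows, in_c)] *= config.cluster_marker_fold
        for label_type, effects in (
            ("disorder", config.disorder_effects),
            ("region", config.region_effects),
        ):
            if effects:
                label = meta_idx.loc[sid, label_type]
                if label in effects:
                    eff_genes, fold = effects[label]
                    rows = genes.get_indexer(pd.Index(eff_genes))
                    if (rows < 0).any():
                        raise KeyError("effect gene not in gene universe")
                    mu[rows, :] *= fold
        lam = rng.gamma(theta, mu / theta)
        counts = rng.poisson(lam).astype(np.int64)
        samples[sid] = CountMatrix(
            sp.csr_matrix(counts), genes, cell_ids[sl]
        )

    base_means = pd.Series(base, index=genes, name="base_mean")
    program_genes = {
        pid: sorted(genes[rows]) for pid, rows in program_rows.items()
    }
    if config.cluster_marker_size > 0:
        cluster_markers = {
            cid: sorted(genes[rows]) for cid, rows in marker_rows.items()
        }
    else:
        # subtype identity is carried by the home programs
        cluster_markers = {
            f"C{c + 1}": sorted(
                g
                for pid, h in home.items()
                if h == c
                for g in program_genes[pid]
            )
            for c in range(config.n_clusters)
        }
    truth = GroundTruth(
        program_genes=program_genes,
        program_active=program_active,
        cluster_of_cell=cell_cluster,
        sample_of_cell=cell_sample,
        cluster_markers=cluster_markers,
        program_home_cluster={pid: f"C{h + 1}" for pid, h in home.items()},
        base_means=base_means,
    )
    return samples, metadata.drop(columns="n_cells"), truth


def _normalize_probs(p: np.ndarray) -> np.ndarray:
    """Validate and normalize a probability vector."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or p.sum() <= 0:
        raise ValueError("label probabilities must be nonnegative, sum > 0")
    return p / p.sum()


def generate_spot_grid(
    n_rows: int,
    n_cols: int,
    region_layout: Mapping[str, tuple[int, int, int, int]],
    marker_map: Mapping[str, Sequence[str]],
    n_background_genes: int = 200,
    base_mean: float = 0.5,
    effect_size: float = 6.0,
    nb_dispersion: float = 2.0,
    library_sd: float = 0.3,
    seed: int = 0,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Generate a rectangular spatial spot grid with region marker contrast.

    ``region_layout`` maps region name -> (row0, row1, col0, col1) half-open
    rectangles that must tile the grid exactly. Spots inside a region
    overexpress that region's marker genes by ``effect_size``.
    """
    paint = np.full((n_rows, n_cols), -1, dtype=int)
    region_names = list(region_layout)
    for k, (r0, r1, c0, c1) in enumerate(region_layout.values()):
        block = paint[r0:r1, c0:c1]
        if (block != -1).any():
            raise ValueError("region rectangles overlap")
        paint[r0:r1, c0:c1] = k
    if (paint == -1).any():
        raise ValueError("region rectangles do not tile the grid")

    marker_genes = [g for r in region_names for g in marker_map.get(r, [])]
    if len(set(marker_genes)) != len(marker_genes):
        raise ValueError("marker gene lists must be disjoint")
    bg = [f"BG{i:05d}" for i in range(n_background_genes)]
    genes = pd.Index(marker_genes + bg)

    rng = np.random.default_rng(seed)
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    region_of_spot = np.array([region_names[paint[r, c]] for r, c in zip(rows, cols)])
    spot_ids = pd.Index([f"spot_{r}_{c}" for r, c in zip(rows, cols)])

    base = rng.lognormal(math.log(base_mean), 0.3, size=len(genes))
    lib = np.exp(rng.normal(0.0, library_sd, size=len(spot_ids)))
    mu = np.outer(base, lib)
    for r in region_names:
        rows_idx = genes.get_indexer(pd.Index(marker_map.get(r, [])))
        in_r = region_of_spot == r
        if len(rows_idx) and in_r.any():
            mu[np.ix_(rows_idx, in_r)] *= effect_size
    lam = rng.gamma(nb_dispersion, mu / nb_dispersion)
    counts = rng.poisson(lam).astype(np.int64)
    cm = CountMatrix(sp.csr_matrix(counts), genes, spot_ids)
    spots = pd.DataFrame(
        {"spot_id": spot_ids, "row": rows, "col": cols, "region": region_of_spot}
    )
    return cm, spots


def generate_proteome(
    modules: Mapping[str, Sequence[str]],
    n_samples_per_group: Mapping[str, int],
    within_module_r: float = 0.6,
    trait_effects: Mapping[str, Mapping[str, float]] | None = None,
    missing_rate: float = 0.0,
    status_shifts: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a module-correlated protein abundance table plus traits.

    Each module has one latent factor per sample; proteins named after the
    module's genes load on it with sqrt(within_module_r), giving pairwise
    within-module correlations ~ within_module_r. ``status_shifts`` moves a
    module's latent factor by case status (the early-shift regime);
    ``trait_effects`` moves continuous traits by status. Missing entries are
    MCAR at ``missing_rate``.
    """
    if not modules or any(len(g) == 0 for g in modules.values()):
        raise ValueError("module gene lists must be non-empty")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    if not 0.0 <= within_module_r <= 1.0:
        raise ValueError("within_module_r must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    statuses, sample_ids = [], []
    for status, n in n_samples_per_group.items():
        for i in range(n):
            sample_ids.append(f"{status}_{i + 1:03d}")
            statuses.append(status)
    n_samples = len(sample_ids)
    status_arr = np.asarray(statuses)

    load = math.sqrt(within_module_r)
    noise = math.sqrt(1.0 - within_module_r)
    rows, names = [], []
    shifts = status_shifts or {}
    for mid, gene_list in modules.items():
        f = rng.normal(0.0, 1.0, size=n_samples)
        for status, delta in shifts.get(mid, {}).items():
            f[status_arr == status] += delta
        for g in gene_list:
            rows.append(load * f + noise * rng.normal(0.0, 1.0, size=n_samples))
            names.append(g)
    abundances = pd.DataFrame(np.asarray(rows), index=pd.Index(names, name="protein"),
                              columns=sample_ids)
    if missing_rate > 0:
        mask = rng.random(abundances.shape) < missing_rate
        abundances = abundances.mask(mask)

    effects = trait_effects or {}
    traits = pd.DataFrame({"sample_id": sample_ids, "status": statuses})
    for t in TRAIT_NAMES:
        shift_by_status = effects.get(t, {})
        delta = np.array([shift_by_status.get(s, 0.0) for s in statuses])
        traits[t] = delta + rng.normal(0.0, 1.0, size=n_samples)
    return abundances, traits
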