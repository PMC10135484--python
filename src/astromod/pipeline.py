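"""End-to-end module discovery: markers -> universe -> NMF -> consensus."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .consensus import (
    ModuleDefinition,
    RankRule,
    SubmoduleLoading,
    assign_module_cells,
    build_gene_universe,
    consensus_cluster,
    define_modules,
    run_cohort_nmf,
)
from .containers import CountMatrix, NormalizedMatrix
from .preprocess import find_markers, lognormalize


@dataclass
class DiscoveryResult:
    markers: pd.DataFrame
    universe: list[str]
    submodules: list[SubmoduleLoading]
    assignments: np.ndarray
    linkage: np.ndarray
    modules: list[ModuleDefinition]
    module_cells: pd.DataFrame
    pooled_norm: NormalizedMatrix = field(repr=False, default=None)


def pool_samples(samples: dict[str, CountMatrix]) -> CountMatrix:
    """Concatenate per-sample count matrices over a shared gene index."""
    mats = list(samples.values())
    genes = mats[0].genes
    for cm in mats[1:]:
        if not cm.genes.equals(genes):
            raise ValueError("samples must share one gene index")
    counts = sp.hstack([cm.counts for cm in mats]).tocsr()
    cells = pd.Index(np.concatenate([cm.cells for cm in mats]))
    return CountMatrix(counts, genes, cells)


def discover_modules(
    samples: dict[str, CountMatrix],
    cell_labels: pd.Series,
    k: int,
    marker_log2fc: float = 0.25,
    universe_log2fc: float = 0.6,
    alpha: float = 0.05,
    rule: RankRule | None = None,
    linkage: str = "average",
    top_n: int = 20,
    cell_threshold: float = 0.7,
    scale_factor: float = 1e4,
    nmf_max_iter: int = 500,
    nmf_tol: float = 1e-5,
    seed: int = 0,
) -> DiscoveryResult:
    """Run the full consensus module discovery over a cohort.

    Cells are pooled to detect subtype markers, the gene universe is the
    union of strong markers (log2FC > universe_log2fc), each sample is
    factorized at its rank, submodules are consensus-clustered into k
    modules, and module cells are assigned under the >= cell_threshold
    expressed-fraction rule on the pooled normalized matrix.
    """
    pooled = pool_samples(samples)
    norm = lognormalize(pooled, scale_factor)
    markers = find_markers(norm, cell_labels, min_log2fc=marker_log2fc, alpha=alpha)
    universe = build_gene_universe(markers, min_log2fc=universe_log2fc, alpha=alpha)
    submodules = run_cohort_nmf(
        samples, universe, rule=rule, scale_factor=scale_factor,
        max_iter=nmf_max_iter, tol=nmf_tol, seed=seed,
    )
    assignments, Z = consensus_cluster(submodules, k=k, linkage=linkage)
    modules = define_modules(assignments, submodules, universe, top_n=top_n)
    module_cells = assign_module_cells(norm, modules, cell_threshold)
    return DiscoveryResult(
        markers=markers,
        universe=universe,
        submodules=submodules,
        assignments=assignments,
        linkage=Z,
        modules=modules,
        module_cells=module_cells,
        pooled_norm=norm,
    )


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def match_modules_to_programs(
    modules: list[ModuleDefinition],
    planted_top: dict[str, list[str]],
) -> dict[str, float]:
    """Best-Jaccard one-to-one matching of planted programs to modules.

    Uses optimal assignment when module and program counts allow, so a
    module cannot absorb two programs; returns Jaccard per program.
    """
    from scipy.optimize import linear_sum_assignment

    programs = list(planted_top)
    J = np.zeros((len(programs), max(len(modules), len(programs))))
    for i, pid in enumerate(programs):
        for j, mod in enumerate(modules):
            J[i, j] = jaccard(planted_top[pid], mod.genes)
    row, col = linear_sum_assignment(-J)
    return {programs[i]: float(J[i, j]) for i, j in zip(row, col)}
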