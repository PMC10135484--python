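"""Consensus NMF module discovery across samples.

Per-sample non-negative matrix factorization of the log-normalized
expression of a shared gene universe, at a rank set by the sample's cell
count (excluded below 100 cells, rank 6 for 100-300, rank 8 above 300).
Every factor's gene-loading vector (a "submodule") is pooled across
samples; submodules are clustered hierarchically on 1 - Pearson distance
and the tree is cut into k consensus modules, each defined by its top
genes under the averaged L1-normalized loadings. A cell is a module cell
iff it expresses at least 70% of the module's defining genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.sparse as sp

from .containers import CountMatrix, NormalizedMatrix
from .preprocess import lognormalize

log = logging.getLogger(__name__)

#: sentinel returned by select_rank for samples below the cell-count floor
EXCLUDED = None


@dataclass
class RankRule:
    min_cells_exclude: int = 100
    rank_low: int = 6
    rank_high: int = 8
    high_threshold: int = 300

    def __post_init__(self) -> None:
        if self.rank_low < 2:
            raise ValueError("rank_low must be >= 2")
        if self.rank_high < self.rank_low:
            raise ValueError("rank_high must be >= rank_low")
        if self.min_cells_exclude > self.high_threshold:
            raise ValueError("min_cells_exclude must be <= high_threshold")


@dataclass
class SubmoduleLoading:
    """One NMF factor's gene-loading vector from one sample."""

    sample_id: str
    factor_index: int
    gene_scores: np.ndarray  # over the shared gene universe, >= 0


@dataclass
class ModuleDefinition:
    """A consensus module: ordered top-N gene list plus membership."""

    module_id: str
    genes: list[str]
    member_submodules: list[int] = field(default_factory=list)
    consensus_scores: pd.Series | None = None


def select_rank(n_cells: int, rule: RankRule | None = None) -> int | None:
    """Decomposition rank from the cell count, or EXCLUDED (None)."""
    rule = rule or RankRule()
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if n_cells < rule.min_cells_exclude:
        return EXCLUDED
    if n_cells <= rule.high_threshold:
        return rule.rank_low
    return rule.rank_high


def build_gene_universe(
    markers: pd.DataFrame, min_log2fc: float = 0.6, alpha: float = 0.05
) -> list[str]:
    """Union of cluster markers passing log2FC > min_log2fc, p_adj < alpha."""
    if markers.empty:
        raise ValueError("marker table is empty")
    keep = markers[(markers["log2fc"] > min_log2fc) & (markers["p_adj"] < alpha)]
    universe = sorted(set(keep["gene"]))
    if not universe:
        raise ValueError(
            "gene universe is empty; relax min_log2fc/alpha thresholds"
        )
    return universe


def nmf_factorize(
    X: np.ndarray | sp.spmatrix,
    rank: int,
    max_iter: int = 500,
    tol: float = 1e-5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multiplicative-update NMF minimizing the Frobenius loss.

    Returns (W, H, loss trace); W columns are rescaled to unit L2 norm with
    the scale absorbed into H. Rows of X that are entirely zero are dropped
    for the updates and re-inserted as zero loadings. Deterministic given
    ``seed``.
    """
    if sp.issparse(X):
        X = np.asarray(X.todense())
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    if X.min() < 0:
        raise ValueError("X must be nonnegative")
    n, m = X.shape
    if rank >= min(n, m):
        raise ValueError(f"rank {rank} must be < min(dims) = {min(n, m)}")
    nonzero_rows = np.flatnonzero(X.sum(axis=1) > 0)
    if len(nonzero_rows) < n:
        log.warning("nmf_factorize: dropped %d all-zero rows", n - len(nonzero_rows))
    Xr = X[nonzero_rows]
    if rank >= min(Xr.shape):
        raise ValueError("rank too large after dropping all-zero rows")

    rng = np.random.default_rng(seed)
    scale = math.sqrt(Xr.mean() / rank)
    W = rng.uniform(1e-4, 1.0, size=(Xr.shape[0], rank)) * scale
    H = rng.uniform(1e-4, 1.0, size=(rank, m)) * scale
    eps = 1e-12
    losses = []
    prev = None
    for _ in range(max_iter):
        W *= (Xr @ H.T) / (W @ (H @ H.T) + eps)
        H *= (W.T @ Xr) / ((W.T @ W) @ H + eps)
        loss = np.linalg.norm(Xr - W @ H)
        losses.append(loss)
        if prev is not None and abs(prev - loss) <= tol * max(prev, eps):
            break
        prev = loss

    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    W = W / norms
    H = H * norms[:, None]
    W_full = np.zeros((n, rank))
    W_full[nonzero_rows] = W
    return W_full, H, np.asarray(losses)


def run_cohort_nmf(
    samples: dict[str, CountMatrix],
    universe: list[str],
    rule: RankRule | None = None,
    scale_factor: float = 1e4,
    max_iter: int = 500,
    tol: float = 1e-5,
    seed: int = 0,
) -> list[SubmoduleLoading]:
    """Per-sample NMF over the gene universe; emit every factor.

    Each retained sample's full count matrix is log-normalized, restricted
    to the universe genes, and factorized at the rank the rule assigns.
    The submodule count equals the sum of per-sample ranks.
    """
    rule = rule or RankRule()
    retained = {
        sid: cm for sid, cm in samples.items()
        if select_rank(cm.n_cells, rule) is not EXCLUDED
    }
    if len(retained) < 2:
        raise ValueError("fewer than two samples pass the rank rule")
    seeds = np.random.SeedSequence(seed).spawn(len(retained))
    submodules: list[SubmoduleLoading] = []
    for (sid, cm), ss in zip(retained.items(), seeds):
        rank = select_rank(cm.n_cells, rule)
        norm = lognormalize(cm, scale_factor)
        X = norm.subset_genes(universe).to_dense()
        W, _, _ = nmf_factorize(
            X, rank, max_iter=max_iter, tol=tol,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        for j in range(rank):
            submodules.append(SubmoduleLoading(sid, j, W[:, j].copy()))
    return submodules


def consensus_cluster(
    submodules: list[SubmoduleLoading],
    k: int,
    linkage: str = "average",
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster submodules on 1 - Pearson distance; cut the tree into k.

    Returns (assignment per submodule, scipy linkage matrix). Assignments
    are 0..k-1 relabeled by order of first appearance; submodules with
    constant gene-score vectors are dropped with a warning and assigned -1.
    """
    S = np.vstack([s.gene_scores for s in submodules])
    sd = S.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        log.warning("consensus_cluster: dropped %d constant submodules",
                    int((~keep).sum()))
    kept_idx = np.flatnonzero(keep)
    if k > len(kept_idx):
        raise ValueError(f"k={k} exceeds the {len(kept_idx)} usable submodules")
    corr = np.corrcoef(S[kept_idx])
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = sch.linkage(condensed, method=linkage)
    raw = sch.fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    assignment = np.full(len(submodules), -1, dtype=int)
    for pos, idx in enumerate(kept_idx):
        lab = raw[pos]
        if lab not in relabel:
            relabel[lab] = len(relabel)
        assignment[idx] = relabel[lab]
    return assignment, Z


def define_modules(
    assignments: np.ndarray,
    submodules: list[SubmoduleLoading],
    universe: list[str],
    top_n: int = 20,
) -> list[ModuleDefinition]:
    """Define each consensus module by its top-N consensus-score genes.

    Each member's gene-score vector is normalized to unit sum and averaged
    across members; genes are ranked by the averaged score, ties broken by
    gene id.
    """
    universe = list(universe)
    modules = []
    for c in sorted(set(assignments) - {-1}):
        members = [i for i, a in enumerate(assignments) if a == c]
        vecs = []
        for i in members:
            v = submodules[i].gene_scores.astype(float)
            s = v.sum()
            vecs.append(v / s if s > 0 else v)
        consensus = np.mean(vecs, axis=0)
        order = sorted(range(len(universe)),
                       key=lambda i: (-consensus[i], universe[i]))
        top = [universe[i] for i in order[:top_n]]
        modules.append(
            ModuleDefinition(
                module_id=f"M{c + 1}",
                genes=top,
                member_submodules=members,
                consensus_scores=pd.Series(consensus, index=universe),
            )
        )
    return modules


def assign_module_cells(
    norm: NormalizedMatrix,
    modules: list[ModuleDefinition],
    threshold_fraction: float = 0.7,
) -> pd.DataFrame:
    """Boolean cells x modules table under the >= 70%-expressed rule.

    A gene is expressed in a cell iff its normalized value is > 0; a cell
    is a module cell iff it expresses at least
    ceil(threshold_fraction * module size) of the module's genes (module
    size counts only genes present in the matrix; missing genes are
    logged).
    """
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    gene_pos = {g: i for i, g in enumerate(norm.genes)}
    detected = (norm.values > 0).tocsr()
    out = {}
    for mod in modules:
        present = [g for g in mod.genes if g in gene_pos]
        if len(present) < len(mod.genes):
            log.warning(
                "assign_module_cells: module %s missing %d genes",
                mod.module_id, len(mod.genes) - len(present),
            )
        if not present:
            out[mod.module_id] = np.zeros(norm.n_cells, dtype=bool)
            continue
        idx = [gene_pos[g] for g in present]
        n_expr = np.asarray(detected[idx].sum(axis=0)).ravel()
        need = math.ceil(threshold_fraction * len(present))
        out[mod.module_id] = n_expr >= need
    return pd.DataFrame(out, index=norm.cells)


def dendrogram_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree."""
    tree = sch.to_tree(Z)

    def render(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left = render(node.get_left())
        right = render(node.get_right())
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    return render(tree) + ";"
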