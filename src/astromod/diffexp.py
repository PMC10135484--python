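"""Region-matched differential expression and module statistics.

DE between disease and control cells is always computed within one brain
region (case and control samples of the same region) to avoid regional
composition confounds. Cross-disorder set logic reports genes shared by at
least a minimum number of disorders along with the exact-subset (UpSet)
decomposition. Module scores are compared between case and control cells
with two-sided Wilcoxon tests, and pairwise module dependency is the
Spearman correlation of per-cell module scores with the +-0.3 / p<0.05
co-occurrent / exclusive classification.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .containers import NormalizedMatrix
from .stats import bonferroni, log2_fold_change, rank_sum_p

log = logging.getLogger(__name__)


@dataclass
class Contrast:
    """One disease-vs-control comparison within a brain region."""

    disorder: str
    region: str
    case_samples: list[str]
    control_samples: list[str]

    def __post_init__(self) -> None:
        if not self.case_samples or not self.control_samples:
            raise ValueError("both contrast sides must be non-empty")


def contrasts_from_metadata(
    metadata: pd.DataFrame, control_label: str = "Control"
) -> list[Contrast]:
    """Build every disorder x region contrast the metadata supports."""
    contrasts = []
    for region, sub in metadata.groupby("region"):
        controls = list(sub.loc[sub["disorder"] == control_label, "sample_id"])
        if not controls:
            log.warning("region %r has no control samples; skipped", region)
            continue
        for disorder, dsub in sub[sub["disorder"] != control_label].groupby("disorder"):
            contrasts.append(
                Contrast(disorder, region, list(dsub["sample_id"]), controls)
            )
    return contrasts


def region_matched_deg(
    norm: NormalizedMatrix,
    sample_of_cell: pd.Series,
    contrasts: Sequence[Contrast],
    min_log2fc: float = 0.25,
    alpha: float = 0.05,
    pseudocount: float | None = None,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Per-contrast gene-level Wilcoxon DE with within-contrast Bonferroni.

    Returns {(disorder, region): table} with columns gene, log2fc, p_raw,
    p_adj and direction in {up, down, ns}: up iff log2FC > min_log2fc and
    p_adj < alpha, down symmetrically.
    """
    sample_of_cell = pd.Series(sample_of_cell).reindex(norm.cells)
    if sample_of_cell.isna().any():
        raise ValueError("sample_of_cell missing for some cells")
    pc = pseudocount if pseudocount is not None else 1.0 / norm.scale_factor
    X = norm.to_dense()
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for ct in contrasts:
        case = sample_of_cell.isin(ct.case_samples).to_numpy()
        ctrl = sample_of_cell.isin(ct.control_samples).to_numpy()
        if case.sum() < 3 or ctrl.sum() < 3:
            log.warning(
                "contrast %s/%s has <3 cells on one side; skipped",
                ct.disorder, ct.region,
            )
            continue
        m_case = np.expm1(X[:, case]).mean(axis=1)
        m_ctrl = np.expm1(X[:, ctrl]).mean(axis=1)
        lfc = log2_fold_change(m_case, m_ctrl, pc)
        p_raw = rank_sum_p(X[:, case], X[:, ctrl])
        p_adj = bonferroni(p_raw, norm.n_genes)
        direction = np.where(
            (lfc > min_log2fc) & (p_adj < alpha), "up",
            np.where((lfc < -min_log2fc) & (p_adj < alpha), "down", "ns"),
        )
        out[(ct.disorder, ct.region)] = pd.DataFrame(
            {
                "gene": norm.genes,
                "log2fc": lfc,
                "p_raw": p_raw,
                "p_adj": p_adj,
                "direction": direction,
            }
        )
    return out


def shared_deg_sets(
    sets: Mapping[str, Iterable[str]], min_disorders: int = 3
) -> tuple[list[str], pd.DataFrame]:
    """Genes shared by >= min_disorders sets plus the UpSet decomposition.

    The combination table counts genes per exact disorder subset; its
    counts sum to the size of the union of all sets.
    """
    if len(sets) < 2:
        raise ValueError("shared_deg_sets needs >= 2 disorders")
    membership: dict[str, set[str]] = {}
    for disorder, genes in sets.items():
        for g in genes:
            membership.setdefault(g, set()).add(disorder)
    shared = sorted(g for g, m in membership.items() if len(m) >= min_disorders)
    combos = Counter(frozenset(m) for m in membership.values())
    table = pd.DataFrame(
        {
            "combination": ["&".join(sorted(c)) for c in combos],
            "n_disorders": [len(c) for c in combos],
            "count": list(combos.values()),
        }
    ).sort_values(["n_disorders", "combination"]).reset_index(drop=True)
    return shared, table


def disorder_pca(
    norm: NormalizedMatrix,
    deg_tables: Mapping[str, pd.DataFrame],
    groups: Mapping[str, Sequence[str]],
    top_n_per_disorder: int = 200,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of sample-group mean expression over top DEGs.

    Features are the union of the top-N genes by |log2FC| per disorder;
    group mean expression is column-standardized and decomposed by SVD.
    Returns the first three component coordinates per group and the
    explained-variance fractions of all components.
    """
    if len(groups) < 4:
        raise ValueError("disorder_pca needs >= 4 sample groups")
    features: set[str] = set()
    for table in deg_tables.values():
        top = table.reindex(
            table["log2fc"].abs().sort_values(ascending=False).index
        ).head(top_n_per_disorder)
        features.update(top["gene"])
    features = sorted(features & set(norm.genes))
    if len(features) < 3:
        raise ValueError("fewer than 3 PCA features")
    sub = norm.subset_genes(features)
    X = sub.to_dense()
    cell_pos = {c: i for i, c in enumerate(norm.cells)}
    M = np.vstack(
        [
            X[:, [cell_pos[c] for c in cells]].mean(axis=1)
            for cells in groups.values()
        ]
    )  # groups x features
    sd = M.std(axis=0)
    keep = sd > 0
    M = (M[:, keep] - M[:, keep].mean(axis=0)) / sd[keep]
    U, S, _ = np.linalg.svd(M, full_matrices=False)
    coords = U[:, :3] * S[:3]
    evr = S**2 / (S**2).sum()
    coord_df = pd.DataFrame(
        coords, index=list(groups), columns=["PC1", "PC2", "PC3"]
    )
    return coord_df, evr


def module_group_test(
    module_scores: pd.DataFrame,
    cell_meta: pd.DataFrame,
    contrasts: Sequence[Contrast],
) -> pd.DataFrame:
    """Two-sided Wilcoxon of per-cell module scores, case vs control.

    ``cell_meta`` must carry a ``sample`` column indexed like the score
    table. Direction is the sign of the median difference.
    """
    cell_meta = cell_meta.reindex(module_scores.index)
    rows = []
    for ct in contrasts:
        case = cell_meta["sample"].isin(ct.case_samples).to_numpy()
        ctrl = cell_meta["sample"].isin(ct.control_samples).to_numpy()
        if case.sum() < 3 or ctrl.sum() < 3:
            log.warning(
                "module_group_test: contrast %s/%s side too small; skipped",
                ct.disorder, ct.region,
            )
            continue
        for mod in module_scores.columns:
            a = module_scores.loc[case, mod].to_numpy()
            b = module_scores.loc[ctrl, mod].to_numpy()
            p = float(rank_sum_p(a, b))
            diff = float(np.median(a) - np.median(b))
            rows.append(
                {
                    "module": mod,
                    "disorder": ct.disorder,
                    "region": ct.region,
                    "p": p,
                    "median_diff": diff,
                    "direction": "up" if diff > 0 else ("down" if diff < 0 else "none"),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class DependencyMatrix:
    """Pairwise module dependency: Spearman r, p, and classification."""

    r: pd.DataFrame
    p: pd.DataFrame
    classification: pd.DataFrame


def module_dependency(
    module_scores: pd.DataFrame,
    r_threshold: float = 0.3,
    alpha: float = 0.05,
) -> DependencyMatrix:
    """Spearman dependency of module score pairs with the +-0.3 rule.

    Pairs with r >= r_threshold and p < alpha are co-occurrent, pairs with
    r <= -r_threshold and p < alpha exclusive, all others neutral.
    Constant score columns yield undefined pairs with a warning.
    """
    if len(module_scores) < 10:
        raise ValueError("module_dependency needs >= 10 cells")
    cols = list(module_scores.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    constant = [c for c in cols if module_scores[c].nunique() <= 1]
    if constant:
        log.warning("module_dependency: constant score columns %s", constant)
    for i in range(k):
        for j in range(i + 1, k):
            if cols[i] in constant or cols[j] in constant:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rij, pij = spearmanr(
                module_scores[cols[i]], module_scores[cols[j]]
            )
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    cls = np.full((k, k), "neutral", dtype=object)
    cls[np.isnan(r)] = "undefined"
    cls[(r >= r_threshold) & (p < alpha)] = "co-occurrent"
    cls[(r <= -r_threshold) & (p < alpha)] = "exclusive"
    return DependencyMatrix(
        r=pd.DataFrame(r, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
        classification=pd.DataFrame(cls, index=cols, columns=cols),
    )
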