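"""Protein-level validation of transcriptomic modules.

A normalized protein abundance table (proteins x samples) is reduced to a
complete-case submatrix, transcriptomic modules are matched to proteins
(validated when at least half their genes are paired, with explicit
per-module exceptions such as a small but functionally coherent module),
and per-sample module abundance scores (means of per-protein z-scores)
are correlated with each other and with neuropathological/cognitive
traits, and compared across case statuses with two-sided Wilcoxon tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .consensus import ModuleDefinition
from .stats import rank_sum_p
from .syndata import TRAIT_NAMES

log = logging.getLogger(__name__)


def filter_complete(
    raw: pd.DataFrame,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Reduce to a complete-case matrix by worst-first greedy removal.

    While missing values remain, the single protein (row) or sample
    (column) with the most missing entries is removed; ties prefer
    proteins. The removal order is returned for audit. Raises if nothing
    survives.
    """
    table = raw.copy()
    removed: list[tuple[str, str]] = []
    while table.isna().to_numpy().any():
        row_miss = table.isna().sum(axis=1)
        col_miss = table.isna().sum(axis=0)
        if row_miss.max() >= col_miss.max():
            victim = row_miss.idxmax()
            table = table.drop(index=victim)
            removed.append(("protein", victim))
        else:
            victim = col_miss.idxmax()
            table = table.drop(columns=victim)
            removed.append(("sample", victim))
        if table.empty:
            raise ValueError("filter_complete removed everything")
    if table.empty:
        raise ValueError("filter_complete removed everything")
    if removed:
        log.info("filter_complete removed %d proteins/samples", len(removed))
    return table, removed


@dataclass
class ModuleProteinMatch:
    module_id: str
    proteins: list[str]
    matched_fraction: float
    validated: bool


def match_module_proteins(
    modules: Sequence[ModuleDefinition] | Mapping[str, Sequence[str]],
    table: pd.DataFrame,
    min_fraction: float = 0.5,
    exceptions: Mapping[str, int] | None = None,
    gene_to_protein: Mapping[str, str] | None = None,
) -> list[ModuleProteinMatch]:
    """Match module genes to proteins; validate by coverage or exception.

    A module is validated iff matched_fraction >= min_fraction, or it has
    an exception entry (module id -> minimum matched count) that it meets.
    Unvalidated modules are flagged and excluded from scoring.
    """
    if not isinstance(modules, Mapping):
        modules = {m.module_id: m.genes for m in modules}
    exceptions = exceptions or {}
    mapping = gene_to_protein or {}
    available = set(table.index)
    out = []
    for mid, genes in modules.items():
        mapped = [mapping.get(g, g) for g in genes]
        matched = [p for p in mapped if p in available]
        frac = len(matched) / len(genes) if genes else 0.0
        validated = frac >= min_fraction or (
            mid in exceptions and len(matched) >= exceptions[mid]
        )
        if not validated:
            log.warning(
                "module %s not validated at the protein level (%d/%d matched)",
                mid, len(matched), len(genes),
            )
        out.append(ModuleProteinMatch(mid, matched, frac, validated))
    return out


def protein_module_score(
    table: pd.DataFrame, matches: Sequence[ModuleProteinMatch]
) -> pd.DataFrame:
    """Per-sample module abundance scores (samples x modules).

    score(sample, module) = mean over matched proteins of the protein's
    z-scored abundance (z across samples). Zero-variance proteins are
    dropped with a warning; only validated modules are scored.
    """
    values = table.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    flat = sd.ravel() == 0
    if flat.any():
        log.warning("protein_module_score: dropped %d zero-variance proteins",
                    int(flat.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z_df = pd.DataFrame(z, index=table.index, columns=table.columns)
    z_df = z_df.loc[~flat]
    scores = {}
    for m in matches:
        if not m.validated:
            continue
        rows = [p for p in m.proteins if p in z_df.index]
        if not rows:
            log.warning("module %s has no usable proteins; skipped", m.module_id)
            continue
        scores[m.module_id] = z_df.loc[rows].mean(axis=0)
    return pd.DataFrame(scores)


@dataclass
class TraitAnalysis:
    """Module-module and module-trait correlations plus status tests."""

    module_r: pd.DataFrame
    module_p: pd.DataFrame
    trait_r: pd.DataFrame
    trait_p: pd.DataFrame
    status_tests: pd.DataFrame


def module_trait_analysis(
    scores: pd.DataFrame,
    traits: pd.DataFrame,
    trait_cols: Sequence[str] | None = None,
) -> TraitAnalysis:
    """Spearman correlations of module scores with each other and with
    continuous traits, plus pairwise case-status Wilcoxon tests.

    ``traits`` must carry sample_id, status, and the continuous trait
    columns; rows are aligned to the score table's sample index. Constant
    traits yield NaN correlations with a warning.
    """
    if len(scores) < 10:
        raise ValueError("module_trait_analysis needs >= 10 samples")
    traits = traits.set_index("sample_id").reindex(scores.index)
    if traits["status"].isna().any():
        raise ValueError("traits missing for some scored samples")
    trait_cols = list(trait_cols or [t for t in TRAIT_NAMES if t in traits])

    mods = list(scores.columns)
    k = len(mods)
    mr = np.eye(k)
    mp = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            rij, pij = spearmanr(scores[mods[i]], scores[mods[j]])
            mr[i, j] = mr[j, i] = rij
            mp[i, j] = mp[j, i] = pij

    tr = np.zeros((k, len(trait_cols)))
    tp = np.zeros((k, len(trait_cols)))
    for j, t in enumerate(trait_cols):
        col = traits[t].to_numpy(dtype=float)
        if np.unique(col).size <= 1:
            log.warning("trait %r is constant; correlation undefined", t)
            tr[:, j] = tp[:, j] = np.nan
            continue
        for i, m in enumerate(mods):
            tr[i, j], tp[i, j] = spearmanr(scores[m], col)

    status = traits["status"]
    rows = []
    for a, b in combinations(pd.unique(status), 2):
        in_a = (status == a).to_numpy()
        in_b = (status == b).to_numpy()
        for m in mods:
            x = scores.loc[in_a, m].to_numpy()
            y = scores.loc[in_b, m].to_numpy()
            p = float(rank_sum_p(x, y))
            rows.append(
                {
                    "module": m,
                    "status_a": a,
                    "status_b": b,
                    "p": p,
                    "median_diff": float(np.median(x) - np.median(y)),
                }
            )
    return TraitAnalysis(
        module_r=pd.DataFrame(mr, index=mods, columns=mods),
        module_p=pd.DataFrame(mp, index=mods, columns=mods),
        trait_r=pd.DataFrame(tr, index=mods, columns=trait_cols),
        trait_p=pd.DataFrame(tp, index=mods, columns=trait_cols),
        status_tests=pd.DataFrame(rows),
    )
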