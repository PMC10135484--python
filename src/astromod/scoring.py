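"""Binned-control signature scoring of cells and spatial spots.

The score of a cell for a signature is the mean log-normalized expression
of the signature genes minus the mean expression of control genes drawn
from the same average-expression bins — the standard binned-control module
score. Region annotation takes the argmax over region signature scores, and
condition comparison of spot scores uses the Kruskal-Wallis test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import kruskal

from .containers import NormalizedMatrix

log = logging.getLogger(__name__)


@dataclass
class GeneSignature:
    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate gene ids")


def score_signature(
    norm: NormalizedMatrix,
    signatures: Sequence[GeneSignature],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    exclude_query_genes: bool = False,
) -> pd.DataFrame:
    """Score every cell for every signature (cells x signatures).

    Genes are ranked by mean expression across cells and cut into
    ``n_bins`` equal-frequency bins. For each signature gene, ``n_ctrl``
    control genes are sampled from its bin (with replacement if the bin is
    smaller than n_ctrl, without otherwise). score(cell) = mean expression
    of signature genes - mean expression of the sampled control genes.
    Deterministic given ``seed`` and the signature order.

    ``exclude_query_genes`` removes the union of all query signatures'
    genes from the control pools, so that a condition-dependent signature
    cannot contaminate the controls of the other signatures scored in the
    same call (cross-contamination control for group comparisons).
    """
    if n_bins < 1 or n_ctrl < 1:
        raise ValueError("n_bins and n_ctrl must be positive")
    X = norm.to_dense()
    avg = X.mean(axis=1)
    order = np.argsort(avg, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(order))
    bin_of_gene = (ranks * n_bins) // len(order)
    in_pool = np.ones(len(order), dtype=bool)
    if exclude_query_genes:
        query = {g for sig in signatures for g in sig.genes}
        in_pool = ~np.isin(norm.genes.to_numpy(), list(query))
    bin_members = {}
    for b in range(n_bins):
        members = np.flatnonzero((bin_of_gene == b) & in_pool)
        if len(members) == 0:  # fall back to the full bin
            members = np.flatnonzero(bin_of_gene == b)
        bin_members[b] = members

    rng = np.random.default_rng(seed)
    gene_pos = {g: i for i, g in enumerate(norm.genes)}
    scores = np.zeros((norm.n_cells, len(signatures)))
    names = []
    for j, sig in enumerate(signatures):
        names.append(sig.name)
        matched = [g for g in sig.genes if g in gene_pos]
        if not matched:
            raise ValueError(f"signature {sig.name!r} has no genes in the matrix")
        if len(matched) < 0.5 * len(sig.genes):
            raise ValueError(
                f"signature {sig.name!r}: fewer than half of its genes are "
                f"present ({len(matched)}/{len(sig.genes)})"
            )
        if len(matched) < len(sig.genes):
            log.warning(
                "signature %r: dropped %d missing genes",
                sig.name, len(sig.genes) - len(matched),
            )
        sig_idx = np.array([gene_pos[g] for g in matched])
        ctrl_idx = []
        for gi in sig_idx:
            members = bin_members[int(bin_of_gene[gi])]
            replace = len(members) < n_ctrl
            ctrl_idx.append(rng.choice(members, size=n_ctrl, replace=replace))
        ctrl_idx = np.concatenate(ctrl_idx)
        scores[:, j] = X[sig_idx].mean(axis=0) - X[ctrl_idx].mean(axis=0)
    return pd.DataFrame(scores, index=norm.cells, columns=names)


def annotate_regions(spot_scores: pd.DataFrame) -> tuple[pd.Series, int]:
    """Label each spot with the argmax region signature.

    Ties are broken by signature (column) order; the number of tied spots
    is returned alongside the labels and logged.
    """
    if spot_scores.shape[1] < 2:
        raise ValueError("annotate_regions needs >= 2 region signatures")
    values = spot_scores.to_numpy()
    best = values.argmax(axis=1)  # first maximum wins
    n_ties = int((values == values.max(axis=1, keepdims=True)).sum(axis=1).__gt__(1).sum())
    if n_ties:
        log.warning("annotate_regions: %d spots had tied top scores", n_ties)
    labels = pd.Series(
        spot_scores.columns.to_numpy()[best], index=spot_scores.index, name="region"
    )
    return labels, n_ties


def compare_spot_conditions(
    scores: pd.DataFrame, condition: pd.Series, min_per_group: int = 5
) -> pd.DataFrame:
    """Kruskal-Wallis test of each signature's scores across conditions."""
    condition = pd.Series(condition).reindex(scores.index)
    if condition.isna().any():
        raise ValueError("condition labels missing for some spots")
    groups = [g for g in pd.unique(condition)]
    if len(groups) < 2:
        raise ValueError("compare_spot_conditions needs >= 2 conditions")
    small = [g for g in groups if (condition == g).sum() < min_per_group]
    if small:
        log.warning(
            "compare_spot_conditions: conditions %s have <%d spots; skipped",
            small, min_per_group,
        )
        groups = [g for g in groups if g not in small]
        if len(groups) < 2:
            raise ValueError("fewer than two conditions with enough spots")
    rows = []
    for col in scores.columns:
        samples = [scores.loc[(condition == g).to_numpy(), col].to_numpy() for g in groups]
        h, p = kruskal(*samples)
        rows.append({"signature": col, "H": h, "p": p})
    return pd.DataFrame(rows)
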