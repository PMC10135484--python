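"""Quality control, log-normalization, HVG selection and marker detection.

QC follows the standard droplet criteria: cells with fewer than 300
detected genes, more than 50,000 total UMIs, or a mitochondrial UMI
fraction of 5% or more are treated as debris/dead cells and removed.
Marker detection is one-vs-rest Wilcoxon rank-sum with Bonferroni
correction over all genes tested in all clusters of one call.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, NormalizedMatrix
from .stats import bonferroni, log2_fold_change, rank_sum_p

log = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    min_genes_per_cell: int = 300
    max_umis_per_cell: int = 50_000
    max_mito_fraction: float = 0.05
    mito_gene_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 0:
            raise ValueError("min_genes_per_cell must be >= 0")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")


def qc_filter(
    counts: CountMatrix, thresholds: QCThresholds | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove low-quality cells; return the filtered matrix and a report.

    A cell is retained iff detected genes >= min_genes_per_cell AND total
    UMIs <= max_umis_per_cell AND mitochondrial fraction < max_mito_fraction.
    The report lists every cell with its metrics and, for removed cells, the
    first failed criterion (low_genes, high_umis, high_mito).
    """
    thresholds = thresholds or QCThresholds()
    csc = counts.counts.tocsc()
    n_detected = np.diff(csc.indptr)
    total = np.asarray(csc.sum(axis=0)).ravel()
    mito_mask = counts.genes.str.startswith(thresholds.mito_gene_prefix)
    if mito_mask.any():
        mito = np.asarray(csc[np.flatnonzero(mito_mask)].sum(axis=0)).ravel()
    else:
        mito = np.zeros_like(total, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)

    low_genes = n_detected < thresholds.min_genes_per_cell
    high_umis = total > thresholds.max_umis_per_cell
    high_mito = mito_frac >= thresholds.max_mito_fraction
    keep = ~(low_genes | high_umis | high_mito)

    reason = np.full(counts.n_cells, "", dtype=object)
    reason[high_mito] = "high_mito"
    reason[high_umis] = "high_umis"
    reason[low_genes] = "low_genes"  # first criterion wins
    report = pd.DataFrame(
        {
            "cell": counts.cells,
            "n_genes": n_detected,
            "n_umis": total,
            "mito_fraction": mito_frac,
            "kept": keep,
            "fail_reason": reason,
        }
    )
    if not keep.any():
        raise ValueError("qc_filter removed all cells")
    filtered = CountMatrix(
        counts.counts[:, np.flatnonzero(keep)], counts.genes, counts.cells[keep]
    )
    return filtered, report


def lognormalize(counts: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """value(g,c) = ln(1 + count(g,c) * scale_factor / libsize(c))."""
    lib = np.asarray(counts.counts.sum(axis=0)).ravel().astype(float)
    if (lib == 0).any():
        bad = counts.cells[lib == 0][0]
        raise ValueError(f"cell {bad!r} has zero library size")
    csc = counts.counts.tocsc().astype(float)
    scaled = csc.multiply(scale_factor / lib)  # column-wise scaling
    scaled = sp.csc_matrix(scaled)
    scaled.data = np.log1p(scaled.data)
    return NormalizedMatrix(
        scaled.tocsr(), counts.genes, counts.cells, scale_factor, libsizes=lib
    )


def _gene_moments(values: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    n = values.shape[1]
    s1 = np.asarray(values.sum(axis=1)).ravel()
    s2 = np.asarray(values.multiply(values).sum(axis=1)).ravel()
    mean = s1 / n
    var = s2 / n - mean**2
    return mean, np.maximum(var, 0.0)


def select_hvg(norm: NormalizedMatrix, n_top: int) -> list[str]:
    """Highly variable genes by standardized variance.

    The log-variance vs log-mean trend is fitted with a quadratic
    polynomial; per-entry standardized values are clipped at sqrt(n_cells)
    and the variance of the clipped values ranks the genes. Ties are broken
    by gene id. A constant matrix yields the first n_top genes with a
    warning.
    """
    if n_top > norm.n_genes:
        raise ValueError("n_top exceeds the number of genes")
    mean, var = _gene_moments(norm.values)
    positive = (var > 0) & (mean > 0)
    if not positive.any():
        log.warning("select_hvg: constant matrix, returning first %d genes", n_top)
        return list(norm.genes[:n_top])
    expected_sd = np.ones(norm.n_genes)
    if np.unique(mean[positive]).size >= 3:
        coef = np.polyfit(np.log10(mean[positive]), np.log10(var[positive]), deg=2)
        expected_sd[positive] = np.sqrt(
            10 ** np.polyval(coef, np.log10(mean[positive]))
        )
    else:  # too few distinct means to fit a trend
        expected_sd[positive] = np.sqrt(var[positive])

    clip = math.sqrt(norm.n_cells)
    n = norm.n_cells
    std_var = np.zeros(norm.n_genes)
    X = norm.values
    for g in np.flatnonzero(positive):
        row = np.asarray(X.getrow(g).todense()).ravel()
        z = np.clip((row - mean[g]) / expected_sd[g], -clip, clip)
        std_var[g] = np.var(z)
    order = sorted(range(norm.n_genes), key=lambda i: (-std_var[i], norm.genes[i]))
    return [norm.genes[i] for i in order[:n_top]]


def find_markers(
    norm: NormalizedMatrix,
    labels: pd.Series,
    min_log2fc: float = 0.25,
    alpha: float = 0.05,
    min_pct: float = 0.10,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """One-vs-rest marker genes per cluster.

    For each cluster with >= 3 cells, every gene detected in at least
    ``min_pct`` of either group is tested with a two-sided Wilcoxon
    rank-sum; Bonferroni correction spans all genes tested in all clusters
    of this call. Records with log2FC > min_log2fc and p_adj < alpha are
    returned, sorted by log2FC descending within cluster.
    """
    labels = pd.Series(labels)
    if not labels.index.equals(norm.cells):
        labels = labels.reindex(norm.cells)
        if labels.isna().any():
            raise ValueError("labels missing for some cells")
    clusters = [c for c in pd.unique(labels)]
    if len(clusters) < 2:
        raise ValueError("find_markers needs at least two clusters")
    pc = pseudocount if pseudocount is not None else 1.0 / norm.scale_factor

    X = norm.to_dense()
    detected = X > 0
    records: list[pd.DataFrame] = []
    n_tests = 0
    for c in clusters:
        in_c = (labels == c).to_numpy()
        if in_c.sum() < 3:
            log.warning("find_markers: cluster %r has <3 cells, skipped", c)
            continue
        if (~in_c).sum() < 3:
            log.warning("find_markers: rest of cluster %r has <3 cells, skipped", c)
            continue
        pct_in = detected[:, in_c].mean(axis=1)
        pct_out = detected[:, ~in_c].mean(axis=1)
        testable = np.maximum(pct_in, pct_out) >= min_pct
        if not testable.any():
            continue
        m_in = np.expm1(X[np.ix_(testable, in_c)]).mean(axis=1)
        m_out = np.expm1(X[np.ix_(testable, ~in_c)]).mean(axis=1)
        lfc = log2_fold_change(m_in, m_out, pc)
        p_raw = rank_sum_p(X[np.ix_(testable, in_c)], X[np.ix_(testable, ~in_c)])
        n_tests += int(testable.sum())
        records.append(
            pd.DataFrame(
                {
                    "gene": norm.genes[testable],
                    "cluster": c,
                    "log2fc": lfc,
                    "p_raw": p_raw,
                    "pct_in": pct_in[testable],
                    "pct_out": pct_out[testable],
                }
            )
        )
    if not records:
        return pd.DataFrame(
            columns=["gene", "cluster", "log2fc", "p_raw", "p_adj", "pct_in", "pct_out"]
        )
    out = pd.concat(records, ignore_index=True)
    out["p_adj"] = bonferroni(out["p_raw"].to_numpy(), n_tests)
    out = out[(out["log2fc"] > min_log2fc) & (out["p_adj"] < alpha)]
    out = out.sort_values(
        ["cluster", "log2fc"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
    return out[["gene", "cluster", "log2fc", "p_raw", "p_adj", "pct_in", "pct_out"]]
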