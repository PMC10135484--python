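"""Shared statistical primitives: rank-sum testing and fold changes.

The two-group test is the two-sided Wilcoxon rank-sum (Mann-Whitney U). For
small untied groups the exact null distribution of U is used; otherwise the
normal approximation with tie correction and continuity correction, matching
the convention of R's wilcox.test.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import mannwhitneyu

#: largest group size for which the exact U distribution is attempted
EXACT_MAX = 25


def rank_sum_p(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p-values, vectorized over the leading axes.

    ``x`` and ``y`` are arrays whose last axis holds the observations of the
    two groups (e.g. genes x cells slices). Returns p-values broadcast over
    the leading axes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.shape[-1], y.shape[-1]
    method = "auto" if max(n, m) <= EXACT_MAX else "asymptotic"
    res = mannwhitneyu(
        x, y, axis=-1, alternative="two-sided", method=method, use_continuity=True
    )
    return np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)


def bonferroni(p_raw: np.ndarray, n_tests: int) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * n_tests)."""
    return np.minimum(1.0, np.asarray(p_raw, dtype=float) * n_tests)


def log2_fold_change(
    mean_a: np.ndarray, mean_b: np.ndarray, pseudocount: float
) -> np.ndarray:
    """log2 ratio of two mean-expression vectors with a shared pseudocount."""
    return np.log2(np.asarray(mean_a) + pseudocount) - np.log2(
        np.asarray(mean_b) + pseudocount
    )


def group_mean_expm1(values_dense: np.ndarray) -> np.ndarray:
    """Mean of expm1(log-normalized values) along cells (axis -1)."""
    return np.expm1(values_dense).mean(axis=-1)
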