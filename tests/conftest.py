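import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from astromod import CohortConfig, CountMatrix, generate_cohort, lognormalize
from astromod.pipeline import pool_samples


@pytest.fixture(scope="session")
def canonical():
    """The canonical cohort: 12 samples, 150-400 cells, 1,000 genes,
    4 disjoint 50-gene programs at 6-fold effect."""
    cfg = CohortConfig(seed=42)
    samples, metadata, truth = generate_cohort(cfg)
    return cfg, samples, metadata, truth


@pytest.fixture(scope="session")
def canonical_norm(canonical):
    _, samples, _, _ = canonical
    return lognormalize(pool_samples(samples))


@pytest.fixture()
def toy_counts():
    """Small deterministic count matrix, 6 genes x 5 cells."""
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 20, size=(6, 5))
    counts[0] += 1  # keep library sizes positive
    genes = pd.Index([f"g{i}" for i in range(6)])
    cells = pd.Index([f"c{i}" for i in range(5)])
    return CountMatrix(sp.csr_matrix(counts), genes, cells)
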