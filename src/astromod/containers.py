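"""Core in-memory containers for the pipeline.

Count and normalized matrices are stored genes x cells (the orientation of
10x-style MTX exports) as scipy CSR sparse matrices with pandas indexes for
gene and cell identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class CountMatrix:
    """Sparse nonnegative integer UMI counts, genes x cells."""

    counts: sp.csr_matrix
    genes: pd.Index
    cells: pd.Index

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.genes = pd.Index(self.genes)
        self.cells = pd.Index(self.cells)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        idx = self.genes.get_indexer(pd.Index(gene_ids))
        if (idx < 0).any():
            missing = list(pd.Index(gene_ids)[idx < 0])
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return CountMatrix(self.counts[idx], pd.Index(gene_ids), self.cells)

    def subset_cells(self, cell_ids) -> "CountMatrix":
        idx = self.cells.get_indexer(pd.Index(cell_ids))
        if (idx < 0).any():
            missing = list(pd.Index(cell_ids)[idx < 0])
            raise KeyError(f"cells not in matrix: {missing[:5]}")
        return CountMatrix(self.counts[:, idx], self.genes, pd.Index(cell_ids))

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


@dataclass
class NormalizedMatrix:
    """Natural-log of (1 + count scaled to a fixed library size), genes x cells.

    value(g, c) = ln(1 + count(g, c) * scale_factor / libsize(c)); sparsity
    pattern equals the count matrix's, so ``value > 0`` iff ``count > 0``.
    """

    values: sp.csr_matrix
    genes: pd.Index
    cells: pd.Index
    scale_factor: float = 1e4
    libsizes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.genes = pd.Index(self.genes)
        self.cells = pd.Index(self.cells)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("values shape does not match gene/cell ids")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def subset_genes(self, gene_ids) -> "NormalizedMatrix":
        idx = self.genes.get_indexer(pd.Index(gene_ids))
        if (idx < 0).any():
            missing = list(pd.Index(gene_ids)[idx < 0])
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return NormalizedMatrix(
            self.values[idx], pd.Index(gene_ids), self.cells, self.scale_factor
        )

    def subset_cells(self, cell_ids) -> "NormalizedMatrix":
        idx = self.cells.get_indexer(pd.Index(cell_ids))
        if (idx < 0).any():
            missing = list(pd.Index(cell_ids)[idx < 0])
            raise KeyError(f"cells not in matrix: {missing[:5]}")
        return NormalizedMatrix(
            self.values[:, idx], self.genes, pd.Index(cell_ids), self.scale_factor
        )

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())
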