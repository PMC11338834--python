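import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scdemon import ExpressionMatrix, SyntheticConfig, generate


def make_matrix(values, gene_ids=None, cell_ids=None, batches=None, **meta_cols):
    """Small helper to build a validated ExpressionMatrix from a dense array."""
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    gene_ids = gene_ids or [f"g{j}" for j in range(g)]
    cell_ids = cell_ids or [f"c{i}" for i in range(n)]
    batches = batches or ["b0"] * n
    meta = pd.DataFrame({"batch_id": batches, **meta_cols}, index=pd.Index(cell_ids, name="cell_id"))
    return ExpressionMatrix(
        values=sp.csr_matrix(values), gene_ids=np.array(gene_ids, dtype=object),
        cell_ids=np.array(cell_ids, dtype=object), cell_meta=meta,
    )


@pytest.fixture
def tiny_matrix():
    """4 cells x 3 genes with two batches."""
    vals = [[2, 0, 1], [0, 3, 0], [1, 1, 0], [0, 0, 4]]
    return make_matrix(vals, batches=["b0", "b0", "b1", "b1"])


@pytest.fixture(scope="session")
def small_planted():
    """Planted-module dataset small enough for per-test reuse."""
    cfg = SyntheticConfig(
        n_cells=1200, n_genes=400, n_modules=3, module_size=40, n_batches=4, seed=11
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def small_null():
    """Independent genes (no planted structure) with a sparsity gradient."""
    cfg = SyntheticConfig(
        n_cells=400, n_genes=300, n_modules=0, module_size=0, n_batches=3,
        sparsity_range=(0.05, 0.95), seed=5,
    )
    return generate(cfg)
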