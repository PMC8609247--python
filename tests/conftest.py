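import numpy as np
import pytest

from embedsep import (
    CellTypeTable,
    EmbeddingTable,
    ExpressionMatrix,
    make_axis_hidden_pair,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def fig2_pair():
    """The axis-hidden pair: overlapping in 2D, z-separated in 3D."""
    return make_axis_hidden_pair(separation=0.5, sigma=0.05, n_per_pop=200, seed=7)


def random_embedding(rng, n_cells=10, ndim=3, with_velocity=False, name="emb"):
    ids = [f"c{i}" for i in range(n_cells)]
    coords = rng.normal(size=(n_cells, ndim))
    vel = rng.normal(size=(n_cells, 3)) if with_velocity else None
    return EmbeddingTable(name, ids, coords, vel)


def random_expression(rng, n_genes=5, n_cells=8, sparsity=0.5):
    genes = [f"g{i}" for i in range(n_genes)]
    cells = [f"c{i}" for i in range(n_cells)]
    values = rng.random(size=(n_genes, n_cells))
    values[rng.random(size=values.shape) < sparsity] = 0.0
    return ExpressionMatrix(genes, cells, values)


def random_celltypes(rng, n_cells=8, n_types=3):
    cells = [f"c{i}" for i in range(n_cells)]
    types = [f"t{i}" for i in range(n_types)]
    membership = (rng.random(size=(n_cells, n_types)) < 0.5).astype(int)
    return CellTypeTable(cells, types, membership)
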