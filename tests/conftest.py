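import numpy as np
import pytest

from scattrib.mlp import Layer, MLPModel
from scattrib import synthetic, io_prep


def random_model(n_in, hidden, n_out, seed=0, zero_bias=False, relu_only=False):
    """Small random network built directly from arrays (test helper)."""
    rng = np.random.default_rng(seed)
    dims = [n_in, *hidden, n_out]
    layers = []
    for a, b in zip(dims[:-1], dims[1:]):
        W = rng.normal(0, 1.0 / np.sqrt(a), size=(a, b))
        bias = np.zeros(b) if zero_bias else rng.normal(0, 0.1, size=b)
        layers.append(Layer(W, bias))
    acts = ["relu" if relu_only else "leaky_relu"] + ["relu"] * (len(hidden) - 1)
    return MLPModel(layers, acts[: len(hidden)], n_in, n_out)


def linear_model(W):
    """Bias-free single linear layer (closed-form oracle for every method)."""
    W = np.asarray(W, dtype=float)
    return MLPModel([Layer(W, np.zeros(W.shape[1]))], [], W.shape[0], W.shape[1])


@pytest.fixture(scope="session")
def separable_data():
    """Strongly separated 3-type dataset plus its marker truth table."""
    cm, truth = synthetic.make_separable(
        n_genes=200, n_cell_types=3, cells_per_type=80, markers_per_type=5, seed=7
    )
    return cm, truth


@pytest.fixture(scope="session")
def separable_lognorm(separable_data):
    cm, truth = separable_data
    return io_prep.log_norm(cm), truth


@pytest.fixture
def tiny_counts():
    """3 genes x 4 cells, two cell types, hand-checkable."""
    counts = np.array([
        [2, 6, 0, 1],
        [2, 2, 3, 0],
        [0, 0, 5, 4],
    ])
    return io_prep.CountMatrix(
        counts=counts,
        gene_ids=np.array(["gA", "gB", "gC"]),
        cell_ids=np.array(["c1", "c2", "c3", "c4"]),
        cell_type=np.array(["T1", "T1", "T2", "T2"]),
    )
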