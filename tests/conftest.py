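import numpy as np
import pytest

from somscape import ExpressionMatrix, SOMGrid, compute_logfc, train_som
from somscape.simulate import generate_differentiation


@pytest.fixture(scope="session")
def small_sim():
    """Small differentiation snapshot shared across unit tests."""
    return generate_differentiation(
        n_cells=200, n_genes=400, n_lineages=2, seed=7
    )


@pytest.fixture(scope="session")
def small_model(small_sim):
    """10x10 SOM trained on the small snapshot."""
    logfc = compute_logfc(small_sim.counts)
    return train_som(logfc, SOMGrid(10, 10), epochs=12, seed=3)


@pytest.fixture(scope="session")
def block_data():
    """Two gene blocks with orthogonal profiles over 6 cells."""
    rng = np.random.default_rng(0)
    a = np.array([3.0, 3.0, 3.0, -3.0, -3.0, -3.0])
    b = np.array([-2.0, 2.0, -2.0, 2.0, -2.0, 2.0])
    rows = [a + rng.normal(0, 0.05, 6) for _ in range(10)]
    rows += [b + rng.normal(0, 0.05, 6) for _ in range(10)]
    vals = np.array(rows)
    vals -= vals.mean(axis=1, keepdims=True)
    return ExpressionMatrix(
        vals, [f"g{i}" for i in range(20)], [f"c{j}" for j in range(6)], "logfc"
    )
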