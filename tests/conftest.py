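import numpy as np
import pytest

from scdml.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """Small 3-batch, 4-type dataset for fast pipeline-level tests."""
    grid = np.full((3, 4), 50, dtype=int)
    cfg = SimConfig(
        n_batches=3, n_types=4, cells_per_type_per_batch=grid,
        n_genes=500, seed=7,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def benchmark_sim():
    """The default benchmark design: 3 batches x 6 types, one rare type,
    one type present in a single batch, ~2,880 cells x 2,000 genes."""
    return simulate(SimConfig(seed=11))


def random_embedding_batches(rng, n, d=8, n_batches=2):
    coords = rng.normal(size=(n, d))
    batch = rng.integers(0, n_batches, size=n)
    # guarantee every batch level non-empty
    batch[:n_batches] = np.arange(n_batches)
    return coords, batch
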