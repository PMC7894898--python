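import numpy as np
import pytest

from scmmst.io_norm import CellDesign, CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_design():
    """12 cells, 3 batches x 2 groups, balanced."""
    batch = [f"b{i % 3}" for i in range(12)]
    group = ["g1" if (i // 3) % 2 == 0 else "g2" for i in range(12)]
    return CellDesign(batch=batch, group=group)


def random_count_matrix(rng, n_genes=8, n_cells=12, mean=3.0):
    vals = rng.poisson(mean, size=(n_genes, n_cells))
    return CountMatrix(
        vals,
        [f"g{i}" for i in range(n_genes)],
        [f"c{j}" for j in range(n_cells)],
    )
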