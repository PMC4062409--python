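import numpy as np
import pytest

from normbench import ExpressionMatrix


def make_matrix(values, groups="AABB", gene_ids=None):
    """Small helper: build an ExpressionMatrix from a 2-D array and a group string."""
    values = np.asarray(values, dtype=float)
    g, a = values.shape
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(g)]
    array_ids = [f"s{j + 1}" for j in range(a)]
    return ExpressionMatrix(
        values, gene_ids, array_ids, dict(zip(array_ids, groups))
    )


@pytest.fixture
def small_matrix():
    """3 genes x 4 arrays, 2 per group."""
    return make_matrix(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0], [0.5, 0.25, 0.75, 1.0]]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240618)


@pytest.fixture
def gaussian_matrix(rng):
    """50 genes x 8 arrays of independent noise, 4 arrays per group."""
    return make_matrix(rng.normal(size=(50, 8)), groups="AAAABBBB")
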