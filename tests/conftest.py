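import numpy as np
import pytest

from mgppm.blocks import Block, Statement


def make_block(slopes, intercepts, traits=None, fmt="RANK", n_categories=None,
               block_id=1):
    """Convenience constructor used across the suite."""
    B = len(slopes)
    if traits is None:
        traits = list(range(B))
    stmts = [
        Statement(statement_id=k + 1, trait=traits[k],
                  slope=slopes[k], intercept=intercepts[k])
        for k in range(B)
    ]
    return Block(block_id, stmts, fmt=fmt, n_categories=n_categories)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def triplet():
    """Three statements on three traits with the study's slope levels."""
    return make_block([0.64, 1.28, 2.0], [0.0, 0.3, -0.2])


@pytest.fixture
def tetrad():
    return make_block([0.8, -1.1, 1.5, 0.9], [0.0, 0.2, -0.4, 0.1])


@pytest.fixture
def pair():
    return make_block([1.0, 1.3], [0.0, -0.25])
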