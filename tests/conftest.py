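import numpy as np
import pytest

from causalem import (
    BipartiteSpec,
    NandSpec,
    StateSpace,
    TransitionModel,
    bipartite_model,
    nand_model,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_random_model(n, rng, full_support=True, labels=None):
    """A random row-stochastic TPM; Dirichlet rows are strictly positive
    unless full_support=False, in which case some entries are zeroed."""
    matrix = rng.dirichlet(np.ones(n), size=n)
    if not full_support:
        mask = rng.random((n, n)) < 0.3
        # never zero out a whole row
        for i in range(n):
            if mask[i].all():
                mask[i, rng.integers(n)] = False
        matrix = np.where(mask, 0.0, matrix)
        matrix = matrix / matrix.sum(axis=1, keepdims=True)
    space = StateSpace.from_labels(labels or [f"s{i}" for i in range(n)])
    return TransitionModel(space, matrix)


@pytest.fixture
def random_model_factory(rng):
    return lambda n, **kw: make_random_model(n, rng, **kw)


@pytest.fixture
def light_switch():
    """Two states: '1' = switch UP / light ON, '0' = DOWN / OFF.
    UP keeps the light ON, DOWN keeps it OFF (an identity dynamic)."""
    space = StateSpace(("0", "1"), bit_width=1)
    return TransitionModel(space, np.eye(2))


@pytest.fixture
def bipartite16():
    return bipartite_model(BipartiteSpec(8, 8, 1.0, 0.0))


@pytest.fixture
def nand2():
    return nand_model(NandSpec(2, 0.1))
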