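import numpy as np
import pytest

from ednaratchet.core import Population
from ednaratchet.edna import EdnaPool


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_class_pop():
    """Half the genomes mutation-free, half carrying one mutation at locus 0."""
    mat = np.zeros((100, 10), dtype=np.int16)
    mat[50:, 0] = 1
    return Population(mat)


@pytest.fixture
def uniform_pool():
    """1000 copies of the zero-mutation allele at each of 10 loci."""
    return EdnaPool.from_entries(10, [(i, 0, 1000) for i in range(10)])
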