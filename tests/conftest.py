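import numpy as np
import pytest

from invadepop import GenotypeMatrix


def make_matrix(calls, samples=None, loci=None) -> GenotypeMatrix:
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    return GenotypeMatrix(
        samples or [f"s{i}" for i in range(n)],
        loci or [f"L{j}" for j in range(L)],
        calls,
    )


@pytest.fixture
def small_matrix():
    # 4 samples x 3 loci, one missing call
    return make_matrix([
        [0, 1, 2],
        [0, 0, 1],
        [1, -1, 0],
        [2, 1, 1],
    ])


@pytest.fixture
def two_pop_matrix():
    """Two disjoint populations fixed for opposite alleles at 20 loci."""
    rng = np.random.default_rng(42)
    a = rng.binomial(2, 0.05, size=(5, 20))
    b = rng.binomial(2, 0.95, size=(5, 20))
    return make_matrix(np.vstack([a, b]))
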