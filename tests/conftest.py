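import numpy as np
import pytest
import scipy.sparse as sp

from topicde.data_model import CountsMatrix


@pytest.fixture
def small_counts() -> CountsMatrix:
    vals = np.array([[1, 2, 0], [3, 4, 0], [0, 1, 5]])
    return CountsMatrix(
        sp.csr_matrix(vals), ["c1", "c2", "c3"], ["g1", "g2", "g3"]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_counts(rng, n=8, m=6, lam=2.0) -> CountsMatrix:
    vals = rng.poisson(lam, size=(n, m))
    return CountsMatrix(
        sp.csr_matrix(vals),
        [f"c{i}" for i in range(n)],
        [f"g{j}" for j in range(m)],
    )
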