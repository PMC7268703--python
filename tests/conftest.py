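import numpy as np
import pytest

from ebaynorm import PhyloTree, fit_dm


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def dm_counts():
    """DM(alpha=(2,5,3)) counts at depth 10000, 2000 samples."""
    rng = np.random.default_rng(7)
    alpha = np.array([2.0, 5.0, 3.0])
    X = np.stack([rng.multinomial(10000, rng.dirichlet(alpha))
                  for _ in range(2000)])
    return X, alpha


@pytest.fixture(scope="session")
def dm_fit(dm_counts):
    X, _ = dm_counts
    return fit_dm(X)


@pytest.fixture
def three_leaf_tree():
    return PhyloTree.from_newick("((l1,l2),l3);", taxa=["l1", "l2", "l3"])


def enumerate_counts(N, p):
    """All nonnegative integer p-vectors summing to N."""
    if p == 1:
        yield (N,)
        return
    for head in range(N + 1):
        for tail in enumerate_counts(N - head, p - 1):
            yield (head, *tail)
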