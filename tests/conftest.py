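import numpy as np
import pytest

from tsbhc.gp import ExpressionMatrix, GPHyperparams, TimeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def grid5():
    return TimeGrid(np.arange(5.0))


@pytest.fixture
def small_matrix(rng, grid5):
    values = rng.standard_normal((4, 5))
    return ExpressionMatrix(values, ("a", "b", "c", "d"), grid5).normalised()


def random_instance(rng, n_max=6, q_max=8):
    """One random (ExpressionMatrix, GPHyperparams) pair for oracle checks."""
    n = int(rng.integers(1, n_max + 1))
    q = int(rng.integers(2, q_max + 1))
    grid = TimeGrid(np.sort(rng.uniform(0, 10, size=q)))
    data = ExpressionMatrix(
        rng.standard_normal((n, q)), tuple(f"g{i}" for i in range(n)), grid
    )
    hyper = GPHyperparams(*np.exp(rng.uniform(-2, 1, size=3)))
    return data, hyper


class FixedEngine:
    """Engine stub returning pre-assigned log H1 values per gene subset.

    Used to decouple the DPM/tree arithmetic from the GP so it can be
    checked against exhaustive partition enumeration.
    """

    def __init__(self, loglik_by_subset):
        self.table = {frozenset(k): float(v) for k, v in loglik_by_subset.items()}
        self.n_evals = 0

    def marginal(self, members, init=None):
        self.n_evals += 1
        return None, self.table[frozenset(members)]


def enumerate_tree_partitions(node):
    """All tree-consistent partitions of a dendrogram node, as lists of
    frozensets (brute-force oracle)."""
    if node.is_leaf:
        return [[node.members]]
    whole = [[node.members]]
    for pl in enumerate_tree_partitions(node.left):
        for pr in enumerate_tree_partitions(node.right):
            whole.append(pl + pr)
    return whole
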