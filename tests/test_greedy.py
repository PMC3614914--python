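import itertools

import numpy as np
import pytest
from scipy.special import gamma

from tsbhc.gp import GPEngine, log_marginal_fast
from tsbhc.greedy import (
    BHCConfig,
    ClusterNode,
    Dendrogram,
    Partition,
    build_greedy_tree,
    cut_dendrogram,
    dpm_merge_prior,
    greedy_bhc,
    init_leaves,
    make_leaf,
    merge_posterior,
)
from tsbhc.synth import adjusted_rand_index, fast_profile, generate_synthetic

from .conftest import FixedEngine, enumerate_tree_partitions


def leaf(i, alpha=1.0, loglik=0.0):
    return ClusterNode(
        members=frozenset([i]),
        log_d=float(np.log(alpha)),
        log_pi=0.0,
        log_like_H1=loglik,
        log_like_tree=loglik,
    )


class TestConfig:
    def test_alpha_positive(self):
        with pytest.raises(ValueError):
            BHCConfig(alpha=0.0)

    def test_threshold_open_interval(self):
        with pytest.raises(ValueError):
            BHCConfig(cut_threshold=1.0)


class TestDPMPrior:
    def test_two_singletons_alpha_one(self):
        # d_k = Gamma(2) + 1 = 2, pi = 0.5
        log_d, log_pi, log_1mpi = dpm_merge_prior(leaf(0), leaf(1), alpha=1.0)
        assert np.exp(log_d) == pytest.approx(2.0)
        assert np.exp(log_pi) == pytest.approx(0.5)
        assert np.exp(log_1mpi) == pytest.approx(0.5)

    def test_leaf_plus_pair_alpha_one(self):
        pair = ClusterNode(
            members=frozenset([0, 1]),
            log_d=float(np.log(2.0)),
            log_pi=float(np.log(0.5)),
            log_like_H1=0.0,
            log_like_tree=0.0,
        )
        log_d, log_pi, _ = dpm_merge_prior(leaf(2), pair, alpha=1.0)
        # d_k = Gamma(3) + 1*2 = 4, pi = 2/4
        assert np.exp(log_d) == pytest.approx(4.0)
        assert np.exp(log_pi) == pytest.approx(0.5)

    def test_rejects_overlap(self):
        with pytest.raises(ValueError):
            dpm_merge_prior(leaf(0), leaf(0), alpha=1.0)

    def test_pi_complement_consistent_when_representable(self):
        log_d, log_pi, log_1mpi = dpm_merge_prior(leaf(0), leaf(1), alpha=0.3)
        assert np.exp(log_pi) + np.exp(log_1mpi) == pytest.approx(1.0)

    def test_log_1mpi_survives_pi_underflow(self):
        # alpha*Gamma(n_k) dominating by hundreds of nats must not zero out
        # the split branch of the tree likelihood
        big = ClusterNode(
            members=frozenset(range(50)),
            log_d=50.0,
            log_pi=0.0,
            log_like_H1=0.0,
            log_like_tree=0.0,
        )
        other = ClusterNode(
            members=frozenset(range(50, 100)),
            log_d=50.0,
            log_pi=0.0,
            log_like_H1=0.0,
            log_like_tree=0.0,
        )
        _, log_pi, log_1mpi = dpm_merge_prior(big, other, alpha=0.001)
        assert np.exp(log_pi) == 1.0  # pi rounds to 1 in double precision
        assert np.isfinite(log_1mpi) and log_1mpi < -100


def brute_force_node_values(node, alpha, h1_table):
    """Exhaustive tree-consistent-partition sums for d_k and p(D|T_k)."""
    d = 0.0
    weighted = 0.0
    for partition in enumerate_tree_partitions(node):
        w = np.prod([alpha * gamma(len(b)) for b in partition])
        d += w
        weighted += w * np.prod([np.exp(h1_table[b]) for b in partition])
    return d, weighted / d


@pytest.mark.parametrize("alpha", [0.1, 1.0, 10.0])
@pytest.mark.parametrize("n_leaves", [2, 3, 4])
def test_tree_likelihood_matches_enumeration(alpha, n_leaves):
    rng = np.random.default_rng(n_leaves * 7 + int(alpha * 10))
    h1 = {}
    for size in range(1, n_leaves + 1):
        for subset in itertools.combinations(range(n_leaves), size):
            h1[frozenset(subset)] = float(rng.uniform(-3, 0))
    engine = FixedEngine(h1)
    config = BHCConfig(alpha=alpha)
    leaves = [
        ClusterNode(
            members=frozenset([i]),
            log_d=float(np.log(alpha)),
            log_pi=0.0,
            log_like_H1=h1[frozenset([i])],
            log_like_tree=h1[frozenset([i])],
        )
        for i in range(n_leaves)
    ]
    tree = build_greedy_tree(leaves, config, engine)
    for node in tree.postorder():
        d_expect, p_expect = brute_force_node_values(node, alpha, h1)
        assert np.exp(node.log_d) == pytest.approx(d_expect, rel=1e-10)
        assert np.exp(node.log_like_tree) == pytest.approx(p_expect, rel=1e-10)


class TestMergePosterior:
    def test_symmetric_case_gives_half(self):
        # pi = 0.5 (two singletons, alpha=1) and H1 = product of children
        h1 = {
            frozenset([0]): -1.0,
            frozenset([1]): -2.0,
            frozenset([0, 1]): -3.0,
        }
        engine = FixedEngine(h1)
        a = leaf(0, loglik=-1.0)
        b = leaf(1, loglik=-2.0)
        node = merge_posterior(a, b, BHCConfig(alpha=1.0), engine)
        assert node.r == pytest.approx(0.5, rel=1e-12)

    def test_r_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            vals = rng.uniform(-10, 0, size=3)
            h1 = {
                frozenset([0]): vals[0],
                frozenset([1]): vals[1],
                frozenset([0, 1]): vals[2],
            }
            node = merge_posterior(
                leaf(0, loglik=vals[0]),
                leaf(1, loglik=vals[1]),
                BHCConfig(alpha=float(rng.uniform(0.01, 10))),
                FixedEngine(h1),
            )
            assert 0.0 < node.r <= 1.0
            for v in (node.log_d, node.log_pi, node.log_like_tree):
                assert np.isfinite(v)


@pytest.fixture(scope="module")
def toy_run():
    cfg = fast_profile(seed=3, n_clusters=2, genes_per_cluster=4, n_times=8)
    data, truth = generate_synthetic(cfg)
    engine = GPEngine(data)
    config = BHCConfig()
    tree = greedy_bhc(data, config, engine)
    return data, truth, config, engine, tree


class TestGreedy:
    def test_structure(self, toy_run):
        data, _, _, _, tree = toy_run
        internal = tree.internal_nodes()
        assert len(internal) == data.n_genes - 1
        for node in internal:
            assert node.members == node.left.members | node.right.members
            assert not (node.left.members & node.right.members)
        assert tree.root.members == frozenset(range(data.n_genes))

    def test_two_separated_clusters(self, toy_run):
        data, truth, _, _, tree = toy_run
        assert tree.root.r < 0.5
        part = cut_dendrogram(tree)
        assert adjusted_rand_index(part, truth) == 1.0

    def test_within_cluster_merges_confident(self, toy_run):
        _, _, _, _, tree = toy_run
        within = [n for n in tree.internal_nodes() if n is not tree.root]
        assert all(n.r > 0.5 for n in within)

    def test_deterministic(self, toy_run):
        data, _, config, _, tree = toy_run
        tree2 = greedy_bhc(data, config, GPEngine(data))
        for a, b in zip(tree.postorder(), tree2.postorder()):
            assert a.members == b.members
            assert a.r == b.r

    def test_two_genes(self, toy_run):
        data, _, config, _, _ = toy_run
        sub = data.subset([0, 1])
        tree = greedy_bhc(sub, config)
        assert tree.root.members == frozenset([0, 1])
        assert tree.root.r is not None

    def test_rejects_single_gene(self, toy_run):
        data, _, config, engine, _ = toy_run
        with pytest.raises(ValueError):
            init_leaves(data.subset([0]), config, engine)


class TestInitLeaves:
    def test_leaf_contract(self, toy_run):
        data, _, config, engine, _ = toy_run
        leaves = init_leaves(data, config, engine)
        assert len(leaves) == data.n_genes
        for i, lf in enumerate(leaves):
            assert lf.members == frozenset([i])
            assert lf.log_pi == 0.0
            assert lf.log_d == pytest.approx(np.log(config.alpha))
            assert lf.log_like_tree == lf.log_like_H1

    def test_leaf_likelihood_matches_gp(self, toy_run):
        data, _, config, engine, _ = toy_run
        lf = init_leaves(data, config, engine)[0]
        assert lf.log_like_H1 == pytest.approx(
            log_marginal_fast(data.subset([0]), lf.hyper), rel=1e-12
        )


def manual_tree(r_root, r_left, r_right):
    leaves = [leaf(i) for i in range(4)]
    lpair = ClusterNode(
        members=frozenset([0, 1]), log_d=0.0, log_pi=0.0,
        log_like_H1=0.0, log_like_tree=0.0, r=r_left,
        left=leaves[0], right=leaves[1],
    )
    rpair = ClusterNode(
        members=frozenset([2, 3]), log_d=0.0, log_pi=0.0,
        log_like_H1=0.0, log_like_tree=0.0, r=r_right,
        left=leaves[2], right=leaves[3],
    )
    root = ClusterNode(
        members=frozenset(range(4)), log_d=0.0, log_pi=0.0,
        log_like_H1=0.0, log_like_tree=0.0, r=r_root,
        left=lpair, right=rpair,
    )
    return Dendrogram(root=root, gene_ids=("a", "b", "c", "d"))


class TestCut:
    def test_all_confident_gives_one_cluster(self):
        part = cut_dendrogram(manual_tree(0.9, 0.9, 0.9))
        assert part.n_clusters == 1

    def test_all_uncertain_gives_singletons(self):
        part = cut_dendrogram(manual_tree(0.1, 0.2, 0.3))
        assert part.n_clusters == 4

    def test_mixed_tree_two_pairs(self):
        part = cut_dendrogram(manual_tree(0.2, 0.9, 0.8))
        clusters = {frozenset(v) for v in part.clusters().values()}
        assert clusters == {frozenset({"a", "b"}), frozenset({"c", "d"})}

    def test_threshold_inclusive(self):
        part = cut_dendrogram(manual_tree(0.5, 0.9, 0.9), threshold=0.5)
        assert part.n_clusters == 1

    def test_conservation(self):
        part = cut_dendrogram(manual_tree(0.2, 0.9, 0.1))
        assert sorted(part.labels) == ["a", "b", "c", "d"]
        groups = part.clusters()
        union = set().union(*groups.values())
        assert union == {"a", "b", "c", "d"}
        assert sum(len(g) for g in groups.values()) == 4


class TestPartition:
    def test_relabel_by_size(self):
        p = Partition({"a": 7, "b": 7, "c": 3, "d": 7}).relabelled_by_size()
        assert p.labels["a"] == p.labels["b"] == p.labels["d"] == 1
        assert p.labels["c"] == 2
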