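"""Greedy Bayesian hierarchical clustering with Dirichlet-process merge priors.

Each gene starts in its own cluster.  A candidate merge of clusters i and j
is scored by the posterior probability r_k that the pooled data were
generated by one latent function:

    r_k = pi_k * p(D_k | H1) / p(D_k | T_k)
    p(D_k | T_k) = pi_k * p(D_k | H1) + (1 - pi_k) * p(D_i | T_i) * p(D_j | T_j)

with the prior weight pi_k = alpha * Gamma(n_k) / d_k and the recursion
d_k = alpha * Gamma(n_k) + d_i * d_j.  The pair with the highest r_k is
merged at each step until one cluster remains; cutting the dendrogram where
r falls below a threshold (default 0.5) yields the flat partition.

All probability arithmetic is carried out in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .gp import ExpressionMatrix, GPEngine, GPHyperparams

__all__ = [
    "BHCConfig",
    "ClusterNode",
    "Dendrogram",
    "Partition",
    "init_leaves",
    "dpm_merge_prior",
    "merge_posterior",
    "greedy_bhc",
    "build_greedy_tree",
    "cut_dendrogram",
]


@dataclass(frozen=True)
class BHCConfig:
    """alpha is the DPM concentration; small values encode weak clustering."""

    alpha: float = 0.001
    cut_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError("alpha must be > 0")
        if not (0.0 < self.cut_threshold < 1.0):
            raise ValueError("cut_threshold must lie in (0, 1)")


@dataclass(eq=False)
class ClusterNode:
    """Dendrogram node: member gene indices plus DPM/likelihood bookkeeping.

    Nodes compare by identity; trees share subtree structure freely.
    """

    members: frozenset
    log_d: float
    log_pi: float
    log_like_H1: float
    log_like_tree: float
    log_1mpi: float = -np.inf  # log(1 - pi); kept separately, as pi -> 1
    # makes log(1 - exp(log_pi)) lose all precision high in the tree
    hyper: GPHyperparams | None = None
    r: float | None = None  # posterior merge probability; internal nodes only
    left: "ClusterNode | None" = None
    right: "ClusterNode | None" = None
    flagged: bool = False  # numerical trouble during (re)computation

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def __repr__(self) -> str:
        return f"ClusterNode(n={self.n_members}, r={self.r})"


@dataclass
class Dendrogram:
    """Binary merge tree over all genes of one expression matrix."""

    root: ClusterNode
    gene_ids: tuple
    merge_order: list = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def postorder(self):
        """All nodes, children before parents."""
        out, stack = [], [(self.root, False)]
        while stack:
            node, seen = stack.pop()
            if seen or node.is_leaf:
                out.append(node)
            else:
                stack.append((node, True))
                stack.append((node.right, False))
                stack.append((node.left, False))
        return out

    def internal_nodes(self):
        return [n for n in self.postorder() if not n.is_leaf]

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]


@dataclass(frozen=True)
class Partition:
    """Flat assignment of every gene id to one cluster label."""

    labels: dict

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", dict(self.labels))

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def clusters(self) -> dict:
        out: dict = {}
        for g, c in self.labels.items():
            out.setdefault(c, set()).add(g)
        return out

    def relabelled_by_size(self) -> "Partition":
        """Clusters renumbered 1..K by decreasing size (ties by member order)."""
        groups = self.clusters()
        order = sorted(groups, key=lambda c: (-len(groups[c]), sorted(groups[c])))
        remap = {c: i + 1 for i, c in enumerate(order)}
        return Partition({g: remap[c] for g, c in self.labels.items()})


def dpm_merge_prior(left: ClusterNode, right: ClusterNode, alpha: float):
    """Log-space DPM recursion: returns (log d_k, log pi_k, log(1 - pi_k)).

    With a = log(alpha * Gamma(n_k)) and b = log(d_i * d_j):
    pi = e^a / (e^a + e^b), so log pi = -log1p(e^(b-a)) and
    log(1 - pi) = -log1p(e^(a-b)) — both exact even when pi is within
    machine epsilon of 0 or 1.
    """
    if left.members & right.members:
        raise ValueError("clusters to merge must have disjoint members")
    n_k = left.n_members + right.n_members
    a = np.log(alpha) + gammaln(n_k)
    b = left.log_d + right.log_d
    log_d = np.logaddexp(a, b)
    log_pi = -np.logaddexp(0.0, b - a)
    log_1mpi = -np.logaddexp(0.0, a - b)
    return float(log_d), float(log_pi), float(log_1mpi)


def init_leaves(
    data: ExpressionMatrix, config: BHCConfig, engine: GPEngine
) -> list:
    """One leaf per gene: d = alpha, pi = 1, H1 marginal optimised per gene."""
    if data.n_genes < 2:
        raise ValueError("need at least 2 genes to cluster")
    log_alpha = float(np.log(config.alpha))
    return [make_leaf(i, log_alpha, engine) for i in range(data.n_genes)]


def make_leaf(index: int, log_alpha: float, engine: GPEngine) -> ClusterNode:
    hyper, loglik = engine.marginal((index,))
    return ClusterNode(
        members=frozenset([index]),
        log_d=log_alpha,
        log_pi=0.0,
        log_like_H1=loglik,
        log_like_tree=loglik,
        hyper=hyper,
    )


def _merge_init(left: ClusterNode, right: ClusterNode) -> GPHyperparams | None:
    # warm-start from the child whose fit is better per gene
    cands = [c for c in (left, right) if c.hyper is not None]
    if not cands:
        return None
    return max(cands, key=lambda c: c.log_like_H1 / c.n_members).hyper


def merge_posterior(
    left: ClusterNode, right: ClusterNode, config: BHCConfig, engine: GPEngine
) -> ClusterNode:
    """Build the candidate node for merging two clusters.

    Optimises GP hyperparameters on the pooled data, then combines the DPM
    prior with the children's tree likelihoods to obtain r_k in (0, 1].
    """
    log_d, log_pi, log_1mpi = dpm_merge_prior(left, right, config.alpha)
    members = left.members | right.members
    hyper, log_h1 = engine.marginal(members, init=_merge_init(left, right))
    merged_term = log_pi + log_h1
    split_term = log_1mpi + left.log_like_tree + right.log_like_tree
    log_tree = float(np.logaddexp(merged_term, split_term))
    r = float(np.exp(merged_term - log_tree))
    return ClusterNode(
        members=members,
        log_d=log_d,
        log_pi=log_pi,
        log_1mpi=log_1mpi,
        log_like_H1=log_h1,
        log_like_tree=log_tree,
        hyper=hyper,
        r=min(r, 1.0),
        left=left,
        right=right,
    )


def _pair_key(a: ClusterNode, b: ClusterNode):
    return tuple(sorted((min(a.members), min(b.members))))


def build_greedy_tree(
    nodes: list, config: BHCConfig, engine: GPEngine, gene_ids: tuple | None = None
) -> Dendrogram:
    """Agglomerate a list of (sub)cluster nodes greedily into one tree.

    Candidate pairs are memoised; after each merge only pairs involving the
    new node are evaluated.  Ties in r break on the lexicographically
    smallest pair of minimum member indices, so the result is deterministic.
    """
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes to agglomerate")
    active = list(nodes)
    merge_order = []
    # keyed by (min member of a, min member of b); unique among active nodes
    candidates: dict = {}

    for i in range(len(active)):
        for j in range(i + 1, len(active)):
            a, b = active[i], active[j]
            candidates[_pair_key(a, b)] = (merge_posterior(a, b, config, engine), a, b)

    while len(active) > 1:
        if not candidates:
            raise RuntimeError("no viable merge candidates remain")
        best, a, b = max(
            candidates.values(),
            key=lambda e: (e[0].r, tuple(-i for i in _pair_key(e[1], e[2]))),
        )
        # drop every candidate touching the two merged nodes
        candidates = {
            k: v
            for k, v in candidates.items()
            if v[1] is not a and v[1] is not b and v[2] is not a and v[2] is not b
        }
        active = [n for n in active if n is not a and n is not b]
        for other in active:
            candidates[_pair_key(best, other)] = (
                merge_posterior(best, other, config, engine),
                best,
                other,
            )
        active.append(best)
        merge_order.append(best)

    if gene_ids is None:
        all_members = sorted(active[0].members)
        gene_ids = tuple(str(m) for m in all_members)
    return Dendrogram(root=active[0], gene_ids=gene_ids, merge_order=merge_order)


def greedy_bhc(
    data: ExpressionMatrix, config: BHCConfig, engine: GPEngine | None = None
) -> Dendrogram:
    """Full greedy BHC over all genes; deterministic for fixed input."""
    if engine is None:
        engine = GPEngine(data)
    leaves = init_leaves(data, config, engine)
    return build_greedy_tree(leaves, config, engine, gene_ids=data.gene_ids)


def cut_dendrogram(tree: Dendrogram, threshold: float = 0.5) -> Partition:
    """Cut into clusters: maximal subtrees whose root has r >= threshold.

    Leaves count as r = 1, so every gene lands in exactly one cluster.
    """
    labels: dict = {}
    next_label = [0]
    stack = [tree.root]
    while stack:
        node = stack.pop()
        keep = node.is_leaf or (node.r is not None and node.r >= threshold)
        if keep:
            label = next_label[0]
            next_label[0] += 1
            for g in node.members:
                labels[tree.gene_ids[g]] = label
        else:
            stack.append(node.left)
            stack.append(node.right)
    return Partition(labels).relabelled_by_size()
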