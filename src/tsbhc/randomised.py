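"""Randomised acceleration of BHC: subset, split, filter, recurse.

For n genes and subset size m the algorithm is:

1. draw a uniform random subset of m genes;
2. run greedy BHC on the subset;
3. route every remaining gene to the left or right child of the subset
   tree's root by comparing singleton-vs-branch merge posteriors;
4. recurse on each branch's full gene set with a fresh subsample, falling
   back to greedy BHC once a branch holds at most m genes;
5. splice the two recursive subtrees under a new root.

Sibling recursions draw from independently spawned random streams, so the
result is reproducible from (data, alpha, m, seed) alone.  By default the
final tree is consolidated: every internal node's statistics are recomputed
bottom-up from its full membership so the 0.5 cut is well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .gp import ExpressionMatrix, GPEngine
from .greedy import (
    BHCConfig,
    ClusterNode,
    Dendrogram,
    _merge_init,
    build_greedy_tree,
    dpm_merge_prior,
    make_leaf,
    merge_posterior,
)

__all__ = [
    "RandomisedConfig",
    "FilterDecision",
    "sample_subset",
    "filter_gene",
    "randomised_bhc",
    "consolidate_tree",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RandomisedConfig:
    m: int = 20
    seed: int = 0
    consolidate: bool = True

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("subset size m must be >= 2")


@dataclass(frozen=True)
class FilterDecision:
    """Routing record for one filtered gene.

    The scores are log predictive Bayes factors of merging the singleton
    into each branch under the single-function hypothesis:
    ``log p(gene u branch | H1) - log p(branch | H1)``.  The full posterior
    r is *not* used here: when one branch is a tight cluster and the other
    a mixture, r compares two astronomically small numbers whose ratio
    tracks branch coherence rather than membership, and routing degrades
    badly.  The predictive ratio normalises the branch's own misfit away.
    """

    gene: int
    branch: str  # "left" | "right"
    score_left: float
    score_right: float


def sample_subset(gene_indices, m: int, rng: np.random.Generator) -> list:
    """Uniform sample of min(m, n) indices without replacement, sorted."""
    idx = sorted(gene_indices)
    if m >= len(idx):
        return idx
    chosen = rng.choice(len(idx), size=m, replace=False)
    return sorted(idx[i] for i in chosen)


def filter_gene(
    gene: int,
    left: ClusterNode,
    right: ClusterNode,
    config: BHCConfig,
    engine: GPEngine,
) -> FilterDecision:
    """Route one gene to the branch with the larger predictive merge score.

    Hyperparameters are re-optimised for each proposed merge (warm-started
    from the branch optimum).  Ties go left.  If the GP fails on one side
    the gene goes to the other side with a warning; failure on both sides
    is a hard error naming the gene.
    """
    scores = {"left": np.nan, "right": np.nan}
    errors = []
    for side, branch in (("left", left), ("right", right)):
        try:
            _, h_branch = engine.marginal(branch.members, init=branch.hyper)
            _, h_merged = engine.marginal(
                branch.members | {gene}, init=branch.hyper
            )
            scores[side] = h_merged - h_branch
        except FloatingPointError as exc:
            errors.append((side, exc))
    if len(errors) == 2:
        raise RuntimeError(f"gene {gene}: GP failed on both branches: {errors}")
    if errors:
        side = errors[0][0]
        log.warning("gene %d: GP failed on %s branch; assigning to other", gene, side)
        branch_name = "right" if side == "left" else "left"
    else:
        branch_name = "left" if scores["left"] >= scores["right"] else "right"
    return FilterDecision(gene, branch_name, scores["left"], scores["right"])


def _splice(
    left: ClusterNode, right: ClusterNode, config: BHCConfig, engine: GPEngine
) -> ClusterNode:
    # full-membership merge statistics at the junction of two recursive trees
    return merge_posterior(left, right, config, engine)


def _rbhc(
    indices: list,
    data: ExpressionMatrix,
    config: BHCConfig,
    engine: GPEngine,
    m: int,
    seed_seq: np.random.SeedSequence,
) -> ClusterNode:
    log_alpha = float(np.log(config.alpha))
    if len(indices) == 1:
        return make_leaf(indices[0], log_alpha, engine)
    if len(indices) <= m:
        leaves = [make_leaf(i, log_alpha, engine) for i in sorted(indices)]
        return build_greedy_tree(leaves, config, engine).root

    rng = np.random.default_rng(seed_seq)
    subset = sample_subset(indices, m, rng)
    sub_leaves = [make_leaf(i, log_alpha, engine) for i in subset]
    sub_tree = build_greedy_tree(sub_leaves, config, engine)
    top_left, top_right = sub_tree.root.left, sub_tree.root.right

    left_set = sorted(top_left.members)
    right_set = sorted(top_right.members)
    for gene in sorted(set(indices) - set(subset)):
        decision = filter_gene(gene, top_left, top_right, config, engine)
        (left_set if decision.branch == "left" else right_set).append(gene)

    if min(len(left_set), len(right_set)) <= max(1, len(indices) // 20):
        log.warning(
            "unbalanced top split: sizes %d / %d", len(left_set), len(right_set)
        )

    child_seeds = seed_seq.spawn(2)
    left_node = _rbhc(sorted(left_set), data, config, engine, m, child_seeds[0])
    right_node = _rbhc(sorted(right_set), data, config, engine, m, child_seeds[1])
    return _splice(left_node, right_node, config, engine)


def randomised_bhc(
    data: ExpressionMatrix,
    config: BHCConfig,
    rcfg: RandomisedConfig,
    engine: GPEngine | None = None,
) -> Dendrogram:
    """Randomised BHC over all genes; equals greedy BHC whenever m >= n."""
    if data.n_genes < 2:
        raise ValueError("need at least 2 genes to cluster")
    if engine is None:
        engine = GPEngine(data)
    seed_seq = np.random.SeedSequence(rcfg.seed)
    root = _rbhc(
        list(range(data.n_genes)), data, config, engine, rcfg.m, seed_seq
    )
    tree = Dendrogram(root=root, gene_ids=data.gene_ids)
    if rcfg.consolidate:
        tree = consolidate_tree(tree, config, engine)
    return tree


def consolidate_tree(
    tree: Dendrogram, config: BHCConfig, engine: GPEngine
) -> Dendrogram:
    """Recompute every internal node's statistics from full memberships.

    Single bottom-up pass: DPM weights, re-optimised H1 marginal, tree
    likelihood and r.  Idempotent; nodes whose GP fails keep their previous
    estimate and are flagged.
    """
    for node in tree.internal_nodes():
        try:
            log_d, log_pi, log_1mpi = dpm_merge_prior(
                node.left, node.right, config.alpha
            )
            hyper, log_h1 = engine.marginal(
                node.members, init=_merge_init(node.left, node.right)
            )
            merged_term = log_pi + log_h1
            split_term = (
                log_1mpi + node.left.log_like_tree + node.right.log_like_tree
            )
            log_tree_like = float(np.logaddexp(merged_term, split_term))
            node.log_d, node.log_pi, node.log_1mpi = log_d, log_pi, log_1mpi
            node.hyper, node.log_like_H1 = hyper, log_h1
            node.log_like_tree = log_tree_like
            node.r = min(float(np.exp(merged_term - log_tree_like)), 1.0)
        except FloatingPointError:
            node.flagged = True
            log.warning("consolidation failed at node %r; keeping estimate", node)
    return tree
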