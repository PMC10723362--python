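"""Split-based tree distances with a random-tree null.

Robinson-Foulds, Jaccard-weighted RF (optimal split matching) and
clustering-information distance, plus normalization by the mean distance of
random tree pairs and a permutation p-value for topological similarity.

Trees are treated as unrooted for split extraction; rooted inputs are
unrooted implicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import linear_sum_assignment

from .exceptions import ConfigError, DomainError, InputError


# ---------------------------------------------------------------------------
# splits

@dataclass(frozen=True)
class SplitSet:
    """Non-trivial bipartitions of a leaf set, canonically oriented."""

    leaves: frozenset[str]
    splits: frozenset[frozenset[str]]  # each stored as the side NOT holding min leaf


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def split_set(tree: dendropy.Tree) -> SplitSet:
    """Extract the non-trivial splits of a (possibly rooted) tree."""
    leaves = leaf_labels(tree)
    n = len(leaves)
    ref = min(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = leaves - clade if ref in clade else clade
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    return SplitSet(leaves, frozenset(splits))


def _check_leaves(s1: SplitSet, s2: SplitSet):
    if s1.leaves != s2.leaves:
        raise InputError("trees have different leaf sets")


def _as_splits(t) -> SplitSet:
    return t if isinstance(t, SplitSet) else split_set(t)


# ---------------------------------------------------------------------------
# metrics

def rf_distance(t1, t2) -> int:
    """Number of splits present in exactly one of the two trees."""
    s1, s2 = _as_splits(t1), _as_splits(t2)
    _check_leaves(s1, s2)
    return len(s1.splits ^ s2.splits)


def _jaccard(a: frozenset, b: frozenset) -> float:
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / len(a | b)


def jrf_split_similarity(x: frozenset, y: frozenset, leaves: frozenset, k: float) -> float:
    """Nye-style split similarity raised to the concession exponent k.

    Best of the two side pairings, scoring each as the worse of its two
    Jaccard overlaps; identical splits score 1.
    """
    xc, yc = leaves - x, leaves - y
    straight = min(_jaccard(x, y), _jaccard(xc, yc))
    crossed = min(_jaccard(x, yc), _jaccard(xc, y))
    return max(straight, crossed) ** k


def _max_weight_matching(weights: np.ndarray) -> float:
    """Maximum-total-weight assignment over a (possibly rectangular) matrix."""
    if weights.size == 0:
        return 0.0
    rows, cols = linear_sum_assignment(-weights)
    return float(weights[rows, cols].sum())


def jrf_distance(t1, t2, k: float = 1.0) -> float:
    """Jaccard-Robinson-Foulds distance via optimal split matching.

    Each matched split pair recovers 2*s^k of the 2-per-pair RF weight;
    distance = |S1| + |S2| - 2 * (max matching score).  As k -> infinity the
    similarity collapses to exact-match indicators and the distance
    approaches RF.
    """
    if k <= 0:
        raise DomainError(f"concession exponent k={k} must be > 0")
    s1, s2 = _as_splits(t1), _as_splits(t2)
    _check_leaves(s1, s2)
    a = sorted(s1.splits, key=sorted)
    b = sorted(s2.splits, key=sorted)
    w = np.array(
        [[jrf_split_similarity(x, y, s1.leaves, k) for y in b] for x in a],
        dtype=float,
    ).reshape(len(a), len(b))
    return len(a) + len(b) - 2.0 * _max_weight_matching(w)


def split_entropy(side: frozenset, n: int) -> float:
    """Entropy (bits) of the two-block leaf partition induced by a split."""
    p = len(side) / n
    return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))


def mutual_clustering_information(x: frozenset, y: frozenset, leaves: frozenset) -> float:
    """Mutual information (bits) between the partitions of two splits."""
    n = len(leaves)
    xc, yc = leaves - x, leaves - y
    mi = 0.0
    for block_x in (x, xc):
        for block_y in (y, yc):
            nxy = len(block_x & block_y)
            if nxy == 0:
                continue
            mi += (nxy / n) * math.log2(nxy * n / (len(block_x) * len(block_y)))
    return max(mi, 0.0)  # clip tiny negative rounding residue


def tree_entropy(s: SplitSet) -> float:
    n = len(s.leaves)
    return sum(split_entropy(side, n) for side in s.splits)


def cid_distance(t1, t2) -> float:
    """Clustering-information distance (bits).

    H(t1) + H(t2) - 2 * max matching of summed mutual clustering
    information over split pairings.
    """
    s1, s2 = _as_splits(t1), _as_splits(t2)
    _check_leaves(s1, s2)
    if len(s1.leaves) < 4:
        raise InputError("clustering information needs >= 4 leaves")
    a = sorted(s1.splits, key=sorted)
    b = sorted(s2.splits, key=sorted)
    w = np.array(
        [[mutual_clustering_information(x, y, s1.leaves) for y in b] for x in a],
        dtype=float,
    ).reshape(len(a), len(b))
    d = tree_entropy(s1) + tree_entropy(s2) - 2.0 * _max_weight_matching(w)
    return max(d, 0.0)


METRICS = {
    "RF": rf_distance,
    "JRF": jrf_distance,
    "CID": cid_distance,
}


# ---------------------------------------------------------------------------
# random trees and the permutation test

def random_tree(
    n_leaves: int,
    seed: int | np.random.Generator,
    labels: list[str] | None = None,
) -> dendropy.Tree:
    """Uniform random labeled binary topology by sequential pair-joining.

    At each step two subtrees are merged, chosen uniformly among remaining
    pairs (coalescent-style), which yields the uniform distribution over
    labeled binary topologies.
    """
    if n_leaves < 4:
        raise DomainError("need at least 4 leaves")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_leaves)]
    elif len(labels) != n_leaves:
        raise InputError("labels length must equal n_leaves")
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = int(min(i, j)), int(max(i, j))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes[j] = merged
        nodes.pop(i)
    newick = nodes[0] + ";"
    return dendropy.Tree.get(data=newick, schema="newick")


@dataclass(frozen=True)
class DistanceResult:
    metric: str
    raw: float
    normalized: float
    p_value: float
    null_mean: float
    n_random: int
    seed: int


def similarity_test(
    t1,
    t2,
    metric: str = "CID",
    n_random: int = 10_000,
    seed: int = 0,
    plus_one: bool = False,
    **metric_kwargs,
) -> DistanceResult:
    """Permutation test of whether two trees are closer than random pairs.

    The null draws ``n_random`` independent pairs of random trees on the
    same leaf set.  normalized = observed / null mean; the p-value is the
    fraction of null pairs strictly below the observed distance
    (``plus_one`` switches to (b + 1)/(N + 1)).
    """
    if metric not in METRICS:
        raise ConfigError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    if n_random < 1:
        raise DomainError("n_random must be >= 1")
    fn = METRICS[metric]
    s1, s2 = _as_splits(t1), _as_splits(t2)
    _check_leaves(s1, s2)
    observed = fn(s1, s2, **metric_kwargs)
    labels = sorted(s1.leaves)
    rng = np.random.default_rng(seed)
    null = np.empty(n_random)
    for i in range(n_random):
        ra = random_tree(len(labels), rng, labels)
        rb = random_tree(len(labels), rng, labels)
        null[i] = fn(ra, rb, **metric_kwargs)
    null_mean = float(null.mean())
    if null_mean == 0:
        raise InputError("degenerate null distribution (mean distance 0)")
    below = int((null < observed).sum())
    p = (below + 1) / (n_random + 1) if plus_one else below / n_random
    return DistanceResult(
        metric=metric,
        raw=float(observed),
        normalized=float(observed) / null_mean,
        p_value=float(p),
        null_mean=null_mean,
        n_random=n_random,
        seed=seed if isinstance(seed, int) else -1,
    )
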