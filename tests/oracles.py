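"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's optimized code paths: assignment
problems are solved by exhaustive enumeration, null distributions by full
permutation, superpositions by scipy's rotation solver.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np
from scipy import stats as sps
from scipy.spatial.transform import Rotation


# ---------------------------------------------------------------------------
# trees

def rooted_shapes(leaves: tuple[str, ...]):
    """All rooted binary tree shapes (as newick fragments) on a leaf set."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for k in range(0, len(rest)):
        for combo in combinations(rest, k):
            left_set = (first,) + combo
            right_set = tuple(x for x in rest if x not in combo)
            if not right_set:
                continue
            for lt in rooted_shapes(left_set):
                for rt in rooted_shapes(right_set):
                    yield f"({lt},{rt})"


def all_unrooted_topologies(labels: list[str]) -> list[str]:
    """Every unrooted binary topology on the labels, as newick strings."""
    if len(labels) < 4:
        raise ValueError("need >= 4 labels")
    return [f"({labels[0]},{shape});" for shape in rooted_shapes(tuple(labels[1:]))]


def exhaustive_assignment_max(weights: np.ndarray) -> float:
    """Maximum-weight injective matching by brute force over all pairings."""
    weights = np.asarray(weights, dtype=float)
    if weights.size == 0:
        return 0.0
    n_rows, n_cols = weights.shape
    if n_rows > n_cols:
        return exhaustive_assignment_max(weights.T)
    best = -np.inf
    for cols in permutations(range(n_cols), n_rows):
        total = sum(weights[r, c] for r, c in enumerate(cols))
        best = max(best, total)
    return float(best)


# ---------------------------------------------------------------------------
# rank statistics

def wilcoxon_less_perm_oracle(ic, cc) -> float:
    """Exact one-sided rank-sum p by enumerating all group assignments."""
    ic, cc = list(ic), list(cc)
    pooled = np.array(ic + cc, dtype=float)
    m = len(ic)
    ranks = sps.rankdata(pooled)
    obs = ranks[:m].sum()
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), m):
        total += 1
        if ranks[list(idx)].sum() <= obs:
            count += 1
    return count / total


def spearman_perm_oracle(x, y) -> tuple[float, float]:
    """Two-sided exact Spearman p over all permutations of y."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rho_obs = sps.spearmanr(x, y).statistic
    count = 0
    total = 0
    for perm in permutations(y):
        total += 1
        r = sps.spearmanr(x, np.array(perm)).statistic
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return float(rho_obs), count / total


# ---------------------------------------------------------------------------
# structures

def tm_refine_oracle(ref_xyz, tgt_xyz, norm_length, d0, cutoff, max_iter=20, tol=1e-6):
    """Independent TM refinement using scipy's rotation solver."""
    ref_xyz = np.asarray(ref_xyz, float)
    tgt_xyz = np.asarray(tgt_xyz, float)

    def superpose(include):
        a = ref_xyz[include]
        b = tgt_xyz[include]
        ac, bc = a.mean(axis=0), b.mean(axis=0)
        rot, _ = Rotation.align_vectors(a - ac, b - bc)
        rmat = rot.as_matrix()
        return rmat, ac - rmat @ bc

    def score(rmat, trans):
        moved = tgt_xyz @ rmat.T + trans
        d = np.linalg.norm(moved - ref_xyz, axis=1)
        return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / norm_length), d

    include = np.ones(len(ref_xyz), dtype=bool)
    best = None
    prev = -np.inf
    for _ in range(max_iter):
        rmat, trans = superpose(include)
        s, d = score(rmat, trans)
        if best is None or s > best:
            best = s
        if abs(s - prev) < tol:
            break
        prev = s
        new_include = d < cutoff
        if new_include.sum() < 3 or np.array_equal(new_include, include):
            break
        include = new_include
    return best
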