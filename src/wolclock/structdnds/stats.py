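"""Bootstrap and rank-based statistics for the omega/structure analyses.

BCa bootstrap confidence intervals, two-group Mann-Whitney / multi-group
Kruskal-Wallis with Dunn's all-pairs follow-up and a compact letter display,
and Spearman rank correlation with an exact small-sample p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

from ..exceptions import DomainError, InputError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# BCa bootstrap

def _adjusted_percentiles(boot: np.ndarray, z0: float, accel: float, level: float):
    """BCa endpoint rule; with z0 = accel = 0 it is the percentile interval."""
    alpha = 1.0 - level
    out = []
    for z_alpha in (sps.norm.ppf(alpha / 2), sps.norm.ppf(1 - alpha / 2)):
        adj = z0 + (z0 + z_alpha) / (1.0 - accel * (z0 + z_alpha))
        out.append(float(np.percentile(boot, 100.0 * sps.norm.cdf(adj))))
    return out[0], out[1]


def bca_interval(
    values,
    statistic,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap interval for a statistic.

    z0 comes from the fraction of bootstrap replicates below the observed
    statistic; the acceleration comes from jackknife skewness.  With
    z0 = a = 0 the interval reduces to the percentile interval on the same
    bootstrap draws.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise DomainError("need at least 2 values")
    if n_boot < 200:
        raise DomainError("need n_boot >= 200")
    if not 0 < level < 1:
        raise DomainError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    theta = float(statistic(values))

    idx = rng.integers(0, n, size=(n_boot, n))
    boot = np.array([float(statistic(values[row])) for row in idx])

    if np.ptp(boot) == 0:
        logger.warning("degenerate bootstrap distribution; zero-width interval")
        return theta, theta

    prop_below = np.mean(boot < theta)
    if prop_below in (0.0, 1.0):
        # observed statistic outside the bootstrap support; fall back to the
        # extreme percentile endpoints
        logger.warning("bias correction is infinite; clamping to bootstrap extremes")
        return float(boot.min()), float(boot.max())
    z0 = sps.norm.ppf(prop_below)

    jack = np.array(
        [float(statistic(np.delete(values, i))) for i in range(n)]
    )
    dev = jack.mean() - jack
    denom = 6.0 * (np.sum(dev**2) ** 1.5)
    accel = float(np.sum(dev**3) / denom) if denom > 0 else 0.0

    return _adjusted_percentiles(boot, float(z0), accel, level)


# ---------------------------------------------------------------------------
# rank-based group comparisons

def _p_adjust(pvals: np.ndarray, method: str) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    order = np.argsort(p)
    adj = np.empty(m)
    if method == "holm":
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p[i])
            adj[i] = min(running, 1.0)
        return adj
    if method == "bh":
        running = 1.0
        for rank, i in enumerate(order[::-1]):
            running = min(running, p[i] * m / (m - rank))
            adj[i] = running
        return adj
    raise DomainError(f"unknown adjustment {method!r}")


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All-pairs Dunn z-tests on pooled ranks with tie correction."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = sps.rankdata(pooled)
    big_n = len(pooled)
    mean_rank = {}
    start = 0
    for g in names:
        size = len(groups[g])
        mean_rank[g] = ranks[start:start + size].mean()
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (big_n - 1))
    var_base = big_n * (big_n + 1) / 12.0 - tie_term
    rows = []
    for a, b in combinations(names, 2):
        var = var_base * (1.0 / len(groups[a]) + 1.0 / len(groups[b]))
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_rank[a] - mean_rank[b]) / np.sqrt(var)
            p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    return pd.DataFrame(rows)


def compact_letter_display(
    names: list[str], significant_pairs: set[tuple[str, str]]
) -> dict[str, str]:
    """Assign letters so that groups share a letter iff not significantly different."""
    columns: list[set[str]] = [set(names)]
    for a, b in significant_pairs:
        new_cols = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb columns contained in another
        columns = []
        for col in sorted(new_cols, key=len, reverse=True):
            if not any(col < other or col == other for other in columns):
                columns.append(col)
    letters = {name: "" for name in names}
    for letter_idx, col in enumerate(columns):
        for name in names:
            if name in col:
                letters[name] += chr(ord("a") + letter_idx)
    return letters


@dataclass
class GroupComparison:
    test: str  # "mann-whitney" | "kruskal-wallis"
    statistic: float
    p_value: float
    groups: list[str]
    group_sizes: dict[str, int]
    pairwise: pd.DataFrame | None
    letters: dict[str, str]
    alpha: float


def group_compare(
    values,
    labels,
    alpha: float = 0.05,
    adjust: str = "holm",
) -> GroupComparison:
    """Rank-based comparison of per-residue medians across labeled groups.

    Two groups: two-sided Mann-Whitney U.  More: Kruskal-Wallis followed by
    all-pairs Dunn tests with multiplicity adjustment.  NA values are
    dropped; groups left with fewer than 2 values are excluded with a
    warning.  Shared letters mark groups not significantly different at
    ``alpha``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    groups: dict[str, np.ndarray] = {}
    for name in pd.unique(labels):
        vals = values[labels == name]
        if len(vals) < 2:
            logger.warning("group %r has <2 usable values; excluded", name)
            continue
        groups[str(name)] = vals
    if len(groups) < 2:
        raise InputError("need at least 2 usable groups")
    names = list(groups)

    pooled = np.concatenate(list(groups.values()))
    degenerate = np.ptp(pooled) == 0

    if len(groups) == 2:
        a, b = groups[names[0]], groups[names[1]]
        if degenerate:
            stat, p = len(a) * len(b) / 2.0, 1.0
        else:
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        sig = {(names[0], names[1])} if p < alpha else set()
        letters = compact_letter_display(names, sig)
        return GroupComparison(
            "mann-whitney", float(stat), float(p), names,
            {g: len(groups[g]) for g in names}, None, letters, alpha,
        )

    if degenerate:
        stat, p = 0.0, 1.0
        pairwise = _dunn_pairwise(groups)
        pairwise["p_adj"] = 1.0
    else:
        stat, p = sps.kruskal(*groups.values())
        pairwise = _dunn_pairwise(groups)
        pairwise["p_adj"] = _p_adjust(pairwise["p_raw"].to_numpy(), adjust)
    sig = {
        (row.group_a, row.group_b)
        for row in pairwise.itertuples()
        if row.p_adj < alpha
    }
    letters = compact_letter_display(names, sig)
    return GroupComparison(
        "kruskal-wallis", float(stat), float(p), names,
        {g: len(groups[g]) for g in names}, pairwise, letters, alpha,
    )


# ---------------------------------------------------------------------------
# Spearman correlation

def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    return float(np.sum(rx * ry) / denom)


def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    p-value is exact (full permutation enumeration, two-sided) for
    n <= ``exact_max_n``; otherwise the t-distribution approximation.
    Returns (nan, nan) with a warning when either variable has zero rank
    variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InputError("need equal-length samples with n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        logger.warning("zero rank variance; correlation undefined")
        return float("nan"), float("nan")
    rho = _rank_corr(rx, ry)
    n = len(x)
    if n <= exact_max_n:
        perms = np.array(list(permutations(ry)))
        xc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        denom = np.sqrt(np.sum(xc**2) * np.sum(pc[0] ** 2))
        rhos = pc @ xc / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return rho, p
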