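"""Scale relative-chronogram posterior samples to absolute time.

Each posterior sample carries a relative chronogram (root age 1) and a
third-position rate multiplier m3 (substitutions per third site per unit
relative time).  Crossing the samples with draws from a substitution-rate
prior gives absolute node ages:

    absolute age = relative age * m3 / rate_draw   [years]

summarized per node by the posterior median and equal-tailed 95% credible
interval.  Weakly supported nodes can be collapsed into polytomies.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .calibration import PriorSpec, sample_prior
from .exceptions import ConfigError, InputError, ValidationError

ULTRAMETRIC_TOL = 1e-6


def _node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            edge = node.edge.length if node.edge.length is not None else 0.0
            if edge < -ULTRAMETRIC_TOL:
                raise ValidationError("negative branch length (child older than parent)")
            depths[node] = depths[node.parent_node] + max(edge, 0.0)
    return depths


def relative_node_ages(tree: dendropy.Tree, tol: float = ULTRAMETRIC_TOL) -> dict[frozenset, float]:
    """Map each internal clade (frozenset of leaf labels) to its relative age.

    Requires an ultrametric tree (all leaves equidistant from the root
    within ``tol``) with root age 1 within ``tol``.
    """
    depths = _node_depths(tree)
    leaf_depths = [d for node, d in depths.items() if node.is_leaf()]
    root_age = max(leaf_depths)
    if root_age <= 0:
        raise ValidationError("tree has zero depth")
    if max(leaf_depths) - min(leaf_depths) > tol * root_age:
        raise ValidationError("tree is not ultrametric beyond tolerance")
    if abs(root_age - 1.0) > 1e-3:
        raise ValidationError(f"relative root age is {root_age:.6g}, expected 1")
    ages: dict[frozenset, float] = {}
    for node, depth in depths.items():
        if node.is_leaf():
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        ages[clade] = root_age - depth
    return ages


@dataclass
class ChronogramSample:
    """One posterior draw: relative tree plus its rate multiplier."""

    tree: dendropy.Tree
    m3: float
    node_ages: dict[frozenset, float]

    @classmethod
    def from_tree(cls, tree: dendropy.Tree, m3: float) -> "ChronogramSample":
        if m3 <= 0:
            raise ValidationError(f"rate multiplier m3={m3} must be > 0")
        return cls(tree=tree, m3=float(m3), node_ages=relative_node_ages(tree))


def read_posterior(trees_path, rates_path) -> list[ChronogramSample]:
    """Read newick posterior trees plus a TSV of per-sample m3 multipliers.

    The TSV needs an ``m3`` column with one row per tree, matched by order.
    """
    trees = dendropy.TreeList.get(path=str(trees_path), schema="newick")
    rates = pd.read_csv(rates_path, sep="\t")
    if "m3" not in rates.columns:
        raise InputError(f"{rates_path}: expected an 'm3' column, found {list(rates.columns)}")
    if len(trees) != len(rates):
        raise InputError(
            f"sample count mismatch: {len(trees)} trees vs {len(rates)} rate rows"
        )
    leaf_sets = {frozenset(lf.taxon.label for lf in t.leaf_node_iter()) for t in trees}
    if len(leaf_sets) > 1:
        raise InputError("posterior trees do not share a common leaf set")
    return [
        ChronogramSample.from_tree(tree, m3)
        for tree, m3 in zip(trees, rates["m3"].to_numpy())
    ]


@dataclass
class AbsoluteChronogramSummary:
    """Consensus topology with absolute node ages in years."""

    topology: dendropy.Tree
    ages: dict[frozenset, float]
    ci_low: dict[frozenset, float]
    ci_high: dict[frozenset, float]
    support: dict[frozenset, float]

    @property
    def root_clade(self) -> frozenset:
        return max(self.ages, key=len)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for clade in sorted(self.ages, key=lambda c: (-len(c), sorted(c))):
            rows.append(
                {
                    "clade": "|".join(sorted(clade)),
                    "age_years": self.ages[clade],
                    "ci_low": self.ci_low[clade],
                    "ci_high": self.ci_high[clade],
                    "support": self.support[clade],
                }
            )
        return pd.DataFrame(rows)


def _node_support(node: dendropy.Node) -> float | None:
    if node.label is not None:
        try:
            return float(node.label)
        except ValueError:
            pass
    ann = node.annotations.get_value("support")
    if ann is not None:
        return float(ann)
    return None


def scale_to_absolute(
    samples: list[ChronogramSample],
    prior: PriorSpec,
    draws_per_sample: int = 100,
    seed: int = 0,
) -> AbsoluteChronogramSummary:
    """Cross posterior samples with rate draws and summarize absolute ages.

    Every sample is combined with ``draws_per_sample`` fresh prior draws
    (rates are drawn positive).  Point estimate = median over the full
    (sample x draw) grid; 95% CI = 2.5/97.5 percentiles.  All samples must
    share one topology - build a consensus upstream if they do not.
    """
    if not samples:
        raise InputError("need at least one posterior sample")
    if draws_per_sample < 1:
        raise ConfigError("draws_per_sample must be >= 1")
    clades = set(samples[0].node_ages)
    for s in samples[1:]:
        if set(s.node_ages) != clades:
            raise InputError(
                "posterior samples disagree in topology; "
                "build a consensus tree upstream before scaling"
            )
    rng = np.random.default_rng(seed)
    per_clade: dict[frozenset, list[np.ndarray]] = {c: [] for c in clades}
    for s in samples:
        rates = sample_prior(prior, draws_per_sample, rng, positive_only=True)
        scale = s.m3 / rates  # years per unit relative time, one per draw
        for clade in clades:
            per_clade[clade].append(s.node_ages[clade] * scale)

    ages, lo, hi = {}, {}, {}
    for clade in clades:
        pooled = np.concatenate(per_clade[clade])
        ages[clade] = float(np.median(pooled))
        lo[clade] = float(np.percentile(pooled, 2.5))
        hi[clade] = float(np.percentile(pooled, 97.5))

    topology = samples[0].tree.clone(depth=1)
    support = {}
    for node in topology.preorder_node_iter():
        if node.is_leaf():
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        sup = _node_support(node)
        support[clade] = 1.0 if sup is None else sup
    return AbsoluteChronogramSummary(topology, ages, lo, hi, support)


def collapse_low_support(tree: dendropy.Tree, threshold: float = 0.95) -> dendropy.Tree:
    """Contract internal edges whose child node support is below threshold.

    Support is read from internal-node labels (newick convention) or a
    ``support`` annotation; a missing value on a non-root internal node is a
    validation error.  The leaf set is unchanged.
    """
    out = tree.clone(depth=1)
    to_collapse = []
    for node in out.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        sup = _node_support(node)
        if sup is None:
            raise ValidationError("internal node lacks a support value")
        if sup < threshold:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return out
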