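"""Seeded generators for every fixture class the analyses consume.

Birth-death trees, GTR+Gamma nucleotide alignments with codon-position rate
multipliers and gamma-relaxed branch rates, codon-level alignments with
regional dN/dS, ideal helical structures, cross-level egg-hatch tables, and
fake relative-chronogram posterior samples.  Everything is deterministic
given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm

from . import ng86
from .chronoscale import ChronogramSample
from .divergence import CodonAlignment, from_records
from .exceptions import DomainError, InputError
from .structdnds import Residue, StructureModel

NT = "ACGT"


# ---------------------------------------------------------------------------
# substitution models

@dataclass(frozen=True)
class EvolutionModel:
    """GTR + Gamma nucleotide model with per-codon-position rate multipliers.

    ``exchangeabilities`` order: (AC, AG, AT, CG, CT, GT).  ``gamma_shape``
    may be ``math.inf`` for rate homogeneity.  Position multipliers are
    normalized to mean 1.
    """

    exchangeabilities: tuple[float, ...] = (1.0,) * 6
    base_freqs: tuple[float, ...] = (0.25,) * 4
    gamma_shape: float = math.inf
    position_multipliers: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if len(self.exchangeabilities) != 6 or any(r <= 0 for r in self.exchangeabilities):
            raise DomainError("need 6 positive exchangeabilities")
        if len(self.base_freqs) != 4 or abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise DomainError("base frequencies must sum to 1")
        if self.gamma_shape <= 0:
            raise DomainError("gamma shape must be positive")
        if any(m <= 0 for m in self.position_multipliers):
            raise DomainError("position multipliers must be positive")
        mean_mult = sum(self.position_multipliers) / 3.0
        if abs(mean_mult - 1.0) > 1e-9:
            object.__setattr__(
                self,
                "position_multipliers",
                tuple(m / mean_mult for m in self.position_multipliers),
            )

    @classmethod
    def jc(cls, gamma_shape: float = math.inf,
           position_multipliers=(1.0, 1.0, 1.0)) -> "EvolutionModel":
        return cls(gamma_shape=gamma_shape, position_multipliers=tuple(position_multipliers))

    def rate_matrix(self) -> np.ndarray:
        """GTR generator scaled to 1 expected substitution per unit time."""
        pi = np.asarray(self.base_freqs)
        ac, ag, at, cg, ct, gt = self.exchangeabilities
        r = np.array(
            [
                [0.0, ac, ag, at],
                [ac, 0.0, cg, ct],
                [ag, cg, 0.0, gt],
                [at, ct, gt, 0.0],
            ]
        )
        q = r * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(pi * np.diag(q)).sum()
        return q / scale

    def spectral(self):
        """(A, lam, Binv) with P(t) = A @ diag(exp(lam t)) @ Binv.

        Uses the reversible symmetrization, so everything stays real.
        """
        pi = np.asarray(self.base_freqs)
        q = self.rate_matrix()
        d = np.sqrt(pi)
        sym = (q * d[:, None]) / d[None, :]
        sym = (sym + sym.T) / 2.0
        lam, v = np.linalg.eigh(sym)
        a = v / d[:, None]
        binv = v.T * d[None, :]
        return a, lam, binv


@dataclass(frozen=True)
class BranchRateModel:
    """Gamma-distributed relaxed branch rates, renormalized to mean 1."""

    shape: float = 7.0
    rate: float = 7.0

    def sample(self, n_branches: int, rng: np.random.Generator) -> np.ndarray:
        raw = rng.gamma(self.shape, 1.0 / self.rate, size=n_branches)
        return raw / raw.mean()


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# trees

class _SimNode:
    __slots__ = ("name", "children", "edge_length", "alive")

    def __init__(self, name=None):
        self.name = name
        self.children = []
        self.edge_length = 0.0
        self.alive = True


def _to_newick(node: _SimNode, extra: float = 0.0) -> str | None:
    if not node.children:
        if not node.alive:
            return None
        return f"{node.name}:{node.edge_length + extra:.10f}"
    parts = [_to_newick(c) for c in node.children]
    parts = [p for p in parts if p is not None]
    if not parts:
        return None
    if len(parts) == 1:
        # suppress the unary node left after pruning an extinct clade
        child = parts[0]
        label, length = child.rsplit(":", 1)
        return f"{label}:{float(length) + node.edge_length + extra:.10f}"
    return f"({','.join(parts)}):{node.edge_length + extra:.10f}"


def sim_tree(n_tips: int, birth: float, death: float = 0.0, seed=0) -> dendropy.Tree:
    """Forward birth-death tree conditioned on ``n_tips`` extant leaves.

    Simulation starts from the root split (two lineages) and stops at the
    first event time after the extant count reaches ``n_tips``; runs whose
    lineages die out are rejected and restarted.  Extinct lineages are
    pruned, so sampling is complete.  Under a pure-birth process the root
    age is sum_{k=2..n} Exp(k * birth).
    """
    if n_tips < 2:
        raise DomainError("need n_tips >= 2")
    if birth <= 0 or death < 0 or death >= birth:
        raise DomainError("need birth > death >= 0")
    rng = _rng(seed)
    while True:
        counter = 0
        root = _SimNode()
        first = [_SimNode(), _SimNode()]
        root.children = first
        active: list[_SimNode] = list(first)
        starts = {id(node): 0.0 for node in first}
        now = 0.0
        failed = False
        while True:
            k = len(active)
            total_rate = k * (birth + death)
            dt = rng.exponential(1.0 / total_rate)
            if k == n_tips:
                now += dt
                break
            now += dt
            idx = int(rng.integers(k))
            node = active[idx]
            if rng.random() < birth / (birth + death):
                node.edge_length = now - starts.pop(id(node))
                kids = [_SimNode(), _SimNode()]
                node.children = kids
                active.pop(idx)
                for kid in kids:
                    active.append(kid)
                    starts[id(kid)] = now
            else:
                node.edge_length = now - starts.pop(id(node))
                node.alive = False
                active.pop(idx)
                if not active:
                    failed = True
                    break
        if failed:
            continue
        for node in active:
            node.edge_length = now - starts[id(node)]
            counter += 1
            node.name = f"t{counter}"
        newick = _to_newick(root)
        assert newick is not None
        # root fragment carries a meaningless trailing length; strip it
        label = newick.rsplit(":", 1)[0]
        return dendropy.Tree.get(data=label + ";", schema="newick")


# ---------------------------------------------------------------------------
# nucleotide alignments

def sim_alignment(
    tree: dendropy.Tree,
    model: EvolutionModel,
    branch_rates: BranchRateModel | None,
    n_codons: int,
    seed=0,
) -> CodonAlignment:
    """Evolve an in-frame alignment along a tree under GTR+Gamma.

    Expected substitutions on a branch at a site are branch length x branch
    rate x gamma site rate x codon-position multiplier.  The process is
    nucleotide-level, so stop codons can arise.
    """
    if n_codons < 1:
        raise DomainError("n_codons must be >= 1")
    rng = _rng(seed)
    n_sites = 3 * n_codons
    a, lam, binv = model.spectral()
    pi = np.asarray(model.base_freqs)

    if math.isinf(model.gamma_shape):
        site_rates = np.ones(n_sites)
    else:
        site_rates = rng.gamma(model.gamma_shape, 1.0 / model.gamma_shape, size=n_sites)
    pos_mult = np.tile(np.asarray(model.position_multipliers), n_codons)
    site_scale = site_rates * pos_mult

    edges = [e for e in tree.preorder_edge_iter() if e.head_node.parent_node is not None]
    if branch_rates is None:
        edge_rate = {id(e): 1.0 for e in edges}
    else:
        rates = branch_rates.sample(len(edges), rng)
        edge_rate = {id(e): r for e, r in zip(edges, rates)}

    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = rng.choice(4, size=n_sites, p=pi)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_states = states[id(node.parent_node)]
        blen = node.edge.length if node.edge.length is not None else 0.0
        t = blen * edge_rate[id(node.edge)] * site_scale
        if blen == 0:
            states[id(node)] = parent_states.copy()
            continue
        probs = np.einsum("sk,kj->sj", a[parent_states] * np.exp(lam[None, :] * t[:, None]), binv)
        probs = np.clip(probs, 0.0, None)
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(n_sites)
        states[id(node)] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)

    records = []
    lut = np.array(list(NT))
    for leaf in tree.leaf_node_iter():
        seq = "".join(lut[states[id(leaf)]])
        records.append((leaf.taxon.label, seq))
    return from_records(records)


def _two_tip_tree(label_a: str, label_b: str, branch_length: float) -> dendropy.Tree:
    nwk = f"({label_a}:{branch_length:.12g},{label_b}:{branch_length:.12g});"
    return dendropy.Tree.get(data=nwk, schema="newick")


def sim_cladogenic_system(
    wol_rate: float,
    nuc_rate: float,
    mt_rate: float,
    T_years: float,
    lengths: tuple[int, int, int] = (10_000, 10_000, 10_000),
    seed=0,
) -> dict[str, CodonAlignment]:
    """Three independent two-tip alignments with divergence 2 * rate * T.

    ``lengths`` are codon counts for the wolbachia/nuclear/mtdna alignments.
    """
    if T_years < 0:
        raise DomainError("T_years must be >= 0")
    rng = _rng(seed)
    out = {}
    for genome, rate, n_codons in zip(
        ("wolbachia", "nuclear", "mtdna"), (wol_rate, nuc_rate, mt_rate), lengths
    ):
        if rate < 0:
            raise DomainError("rates must be >= 0")
        if 2.0 * rate * T_years >= 0.75:
            raise DomainError(
                f"{genome}: expected divergence 2rT = {2 * rate * T_years:.3f} saturates"
            )
        tree = _two_tip_tree(f"{genome}_a", f"{genome}_b", rate * T_years)
        out[genome] = sim_alignment(tree, EvolutionModel.jc(), None, n_codons, rng)
    return out


# ---------------------------------------------------------------------------
# codon-level simulation with regional omega

SENSE_CODONS = tuple(
    c
    for c in (x + y + z for x in NT for y in NT for z in NT)
    if not ng86.is_stop(c)
)
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


def _codon_rate_matrix(omega: float) -> np.ndarray:
    """Goldman-Yang-style generator over sense codons (no stop transitions)."""
    n = len(SENSE_CODONS)
    q = np.zeros((n, n))
    for i, ci in enumerate(SENSE_CODONS):
        for pos in range(3):
            for base in NT:
                if base == ci[pos]:
                    continue
                cj = ci[:pos] + base + ci[pos + 1:]
                if ng86.is_stop(cj):
                    continue
                j = _CODON_INDEX[cj]
                syn = ng86.translate(ci) == ng86.translate(cj)
                q[i, j] = 1.0 if syn else omega
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _neutral_scale() -> float:
    q1 = _codon_rate_matrix(1.0)
    return float(-np.diag(q1).mean())


def expand_omega_profile(regions) -> np.ndarray:
    """Accept either per-codon omegas or [(n_codons, omega), ...] regions."""
    regions = list(regions)
    if regions and isinstance(regions[0], (tuple, list)):
        return np.concatenate([np.full(int(n), float(w)) for n, w in regions])
    return np.asarray(regions, dtype=float)


def sim_codon_pair_omega(omega_profile, t: float, seed=0) -> CodonAlignment:
    """Two-tip codon alignment honoring a per-region dN/dS profile.

    ``t`` is the total path divergence in expected substitutions per codon
    under the neutral (omega = 1) normalization; nonsynonymous rates scale
    with the regional omega, synonymous rates do not.
    """
    omegas = expand_omega_profile(omega_profile)
    if (omegas < 0).any():
        raise DomainError("omega values must be >= 0")
    if t <= 0:
        raise DomainError("divergence scale t must be > 0")
    rng = _rng(seed)
    scale = _neutral_scale()
    transition = {}
    for w in np.unique(omegas):
        q = _codon_rate_matrix(float(w)) / scale
        transition[float(w)] = expm(q * (t / 2.0))
    n_codons = len(omegas)
    ancestor = rng.integers(len(SENSE_CODONS), size=n_codons)
    seqs = {"a": [], "b": []}
    for label in ("a", "b"):
        for i in range(n_codons):
            p = transition[float(omegas[i])][ancestor[i]]
            state = int(rng.choice(len(SENSE_CODONS), p=p / p.sum()))
            seqs[label].append(SENSE_CODONS[state])
    return from_records([("a", "".join(seqs["a"])), ("b", "".join(seqs["b"]))])


# ---------------------------------------------------------------------------
# structures

HELIX_RADIUS = 2.3       # angstrom
HELIX_RISE = 1.5         # angstrom per residue
HELIX_TWIST = 100.0      # degrees per residue


def sim_helix(n_residues: int, confidence: float = 90.0) -> StructureModel:
    """Ideal alpha-helix with closed-form pairwise geometry."""
    if n_residues < 2:
        raise DomainError("need at least 2 residues")
    residues = []
    for i in range(n_residues):
        theta = math.radians(HELIX_TWIST * i)
        coord = np.array(
            [HELIX_RADIUS * math.cos(theta), HELIX_RADIUS * math.sin(theta), HELIX_RISE * i]
        )
        residues.append(Residue(index=i + 1, aa="A", coord=coord, confidence=confidence))
    return StructureModel(tuple(residues))


# ---------------------------------------------------------------------------
# hatch tables

def sim_hatch(
    n_ic: int,
    n_cc: int,
    p_ic: float,
    p_cc: float,
    eggs_low: int = 5,
    eggs_high: int = 15,
    seed=0,
    concentration: float = 5.0,
    n_days: int = 5,
) -> pd.DataFrame:
    """Binomial egg-hatch table with cross-level beta overdispersion.

    Per cross, a hatch probability is drawn from Beta with the group mean
    and the given concentration; daily egg counts are uniform integers in
    [eggs_low, eggs_high].
    """
    for p in (p_ic, p_cc):
        if not 0 <= p <= 1:
            raise DomainError("hatch probabilities must be in [0, 1]")
    if not 0 < eggs_low <= eggs_high:
        raise DomainError("invalid egg-count range")
    rng = _rng(seed)
    rows = []
    for cross_type, n_crosses, p in (("IC", n_ic, p_ic), ("CC", n_cc, p_cc)):
        for c in range(n_crosses):
            if p in (0.0, 1.0):
                p_cross = p
            else:
                p_cross = rng.beta(p * concentration, (1 - p) * concentration)
            for day in range(1, n_days + 1):
                eggs = int(rng.integers(eggs_low, eggs_high + 1))
                hatched = int(rng.binomial(eggs, p_cross))
                rows.append(
                    {
                        "cross_id": f"{cross_type}{c + 1}",
                        "type": cross_type,
                        "day": day,
                        "eggs": eggs,
                        "hatched": hatched,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# chronogram posterior samples

def _ages_to_tree(template: dendropy.Tree, ages: dict[frozenset, float]) -> dendropy.Tree:
    tree = template.clone(depth=1)
    node_age = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node_age[id(node)] = 0.0
        else:
            clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
            node_age[id(node)] = ages[clade]
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node_age[id(node.parent_node)] - node_age[id(node)]
    return tree


def sim_posterior(
    true_tree: dendropy.Tree,
    n_samples: int,
    age_jitter: float,
    m3_mean: float,
    seed=0,
    m3_sigma: float = 0.1,
) -> list[ChronogramSample]:
    """Fake posterior: jittered relative node ages plus lognormal m3 draws.

    Internal node ages are perturbed multiplicatively (lognormal with
    sigma = ``age_jitter``), renormalized to root age 1 and clipped to keep
    children no older than parents.  m3 draws are lognormal with mean
    ``m3_mean``.
    """
    if age_jitter < 0:
        raise DomainError("age_jitter must be >= 0")
    if m3_mean <= 0:
        raise DomainError("m3_mean must be > 0")
    rng = _rng(seed)
    tree = true_tree.clone(depth=1)
    depths = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depths[id(node)] = 0.0 if parent is None else (
            depths[id(parent)] + (node.edge.length or 0.0)
        )
    root_age = max(d for n, d in ((nd, depths[id(nd)]) for nd in tree.leaf_node_iter()))
    base_ages = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        base_ages[clade] = (root_age - depths[id(node)]) / root_age

    root_clade = max(base_ages, key=len)
    samples = []
    for _ in range(n_samples):
        jittered = {
            clade: age * float(rng.lognormal(0.0, age_jitter)) if age_jitter > 0 else age
            for clade, age in base_ages.items()
        }
        norm = jittered[root_clade]
        jittered = {c: a / norm for c, a in jittered.items()}
        # enforce parent >= child top-down
        for clade in sorted(jittered, key=len, reverse=True):
            parents = [c for c in jittered if len(c) > len(clade) and clade < c]
            if parents:
                cap = min(jittered[c] for c in parents)
                jittered[clade] = min(jittered[clade], cap)
        sample_tree = _ages_to_tree(tree, jittered)
        mu = math.log(m3_mean) - m3_sigma**2 / 2.0
        m3 = float(rng.lognormal(mu, m3_sigma))
        samples.append(ChronogramSample.from_tree(sample_tree, m3))
    return samples


def write_posterior(samples: list[ChronogramSample], trees_path, rates_path):
    """Write posterior samples as a newick list plus an m3 TSV."""
    if not samples:
        raise InputError("no samples to write")
    with open(trees_path, "w") as fh:
        for s in samples:
            fh.write(s.tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n")
    pd.DataFrame({"sample": range(len(samples)), "m3": [s.m3 for s in samples]}).to_csv(
        rates_path, sep="\t", index=False
    )
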