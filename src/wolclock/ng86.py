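"""Nei-Gojobori (1986)-style codon counting primitives.

Per-codon synonymous/nonsynonymous site counts and pathway-averaged
substitution counts, shared by the pairwise divergence estimators and the
structure-windowed dN/dS profiles.

Conventions:

* Site counts: at each codon position the synonymous fraction is the number
  of the three possible single-nucleotide changes that preserve the amino
  acid, divided by 3.  Changes creating a stop codon count as nonsynonymous,
  so N + S == 3 exactly for every fully resolved sense codon.
* Multi-hit codons: observed differences are averaged with equal weight over
  all minimal substitution pathways that do not pass through a stop codon;
  if every pathway passes through a stop, all pathways are used.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

_table = CodonTable.unambiguous_dna_by_id[1]  # standard genetic code

#: codon -> one-letter amino acid, with '*' for stop codons
GENETIC_CODE: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    GENETIC_CODE[_stop] = "*"


def translate(codon: str) -> str:
    """One-letter amino acid for a fully resolved codon ('*' = stop)."""
    return GENETIC_CODE[codon]


def is_resolved(codon: str) -> bool:
    """True when all three bases are unambiguous nucleotides."""
    return len(codon) == 3 and all(b in NUCLEOTIDES for b in codon)


def is_stop(codon: str) -> bool:
    return GENETIC_CODE.get(codon) == "*"


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """(S, N) synonymous/nonsynonymous site counts for one sense codon.

    S + N == 3 exactly; mutations to stop codons are nonsynonymous.
    """
    if not is_resolved(codon):
        raise ValueError(f"unresolved codon {codon!r}")
    if is_stop(codon):
        raise ValueError(f"stop codon {codon!r} has no site counts")
    aa = translate(codon)
    syn = 0
    for pos in range(3):
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if translate(mutant) == aa:
                syn += 1
    s = syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def codon_diff_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) observed synonymous/nonsynonymous differences between codons.

    Averaged with equal weight over minimal substitution pathways avoiding
    stop codons (all pathways used if none avoid stops).  Symmetric in its
    arguments.
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0

    paths = []
    for order in permutations(diff_positions):
        current = codon_a
        steps = []  # (syn?, intermediate-is-stop?)
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            syn = translate(current) == translate(nxt)
            if is_stop(nxt) and nxt != codon_b:
                through_stop = True
            steps.append(syn)
            current = nxt
        paths.append((through_stop, steps))

    usable = [steps for through_stop, steps in paths if not through_stop]
    if not usable:
        usable = [steps for _, steps in paths]

    sd = sum(sum(1.0 for syn in steps if syn) for steps in usable) / len(usable)
    total = float(len(diff_positions))
    return sd, total - sd


def pair_codon_counts(codon_a: str, codon_b: str) -> tuple[float, float, float, float]:
    """(S_sites, N_sites, S_diff, N_diff) for one aligned codon pair.

    Site counts are the average of the two codons' counts (NG86).  Raises
    ValueError on unresolved or stop codons; callers decide the skip policy.
    """
    sa, na = codon_site_counts(codon_a)
    sb, nb = codon_site_counts(codon_b)
    sd, nd = codon_diff_counts(codon_a, codon_b)
    return (sa + sb) / 2.0, (na + nb) / 2.0, sd, nd
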