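"""Pairwise divergence from in-frame codon alignments.

Jukes-Cantor-corrected third-position divergence, NG86 synonymous-site
divergence, and the endosymbiont/nuclear/mtDNA ratio table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio import SeqIO

from . import ng86
from .exceptions import (
    DegenerateInputError,
    DomainError,
    FormatError,
    InputError,
    SaturationError,
)

logger = logging.getLogger(__name__)

IUPAC_ALLOWED = set("ACGTN-")
UNAMBIGUOUS = set("ACGT")

GENOMES = ("wolbachia", "nuclear", "mtdna")
RATIOS = (("wolbachia", "nuclear"), ("mtdna", "wolbachia"), ("mtdna", "nuclear"))


@dataclass(frozen=True)
class CodonAlignment:
    """Equal-length nucleotide sequences with codon-position bookkeeping."""

    taxa: tuple[str, ...]
    sequences: tuple[str, ...]
    frame_offset: int = 0

    def __post_init__(self):
        if len(self.taxa) < 2:
            raise InputError("alignment needs at least 2 records")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise FormatError(f"records have unequal lengths: {sorted(lengths)}")
        if self.frame_offset not in (0, 1, 2):
            raise DomainError(f"frame_offset must be 0, 1 or 2, got {self.frame_offset}")
        for name, seq in zip(self.taxa, self.sequences):
            bad = set(seq) - IUPAC_ALLOWED
            if bad:
                raise FormatError(f"record {name!r} contains non-IUPAC characters {sorted(bad)}")

    @property
    def length_nt(self) -> int:
        return len(self.sequences[0])

    @property
    def n_codons(self) -> int:
        return (self.length_nt - self.frame_offset) // 3

    def index(self, label: str) -> int:
        try:
            return self.taxa.index(label)
        except ValueError:
            raise InputError(f"taxon {label!r} not in alignment") from None

    def coding_region(self, label: str) -> str:
        """In-frame portion of a sequence (incomplete trailing codon dropped)."""
        seq = self.sequences[self.index(label)]
        start = self.frame_offset
        return seq[start:start + 3 * self.n_codons]

    def codons(self, label: str) -> list[str]:
        region = self.coding_region(label)
        return [region[i:i + 3] for i in range(0, len(region), 3)]


@dataclass(frozen=True)
class DivergenceEstimate:
    pair: tuple[str, str]
    sites_compared: int
    p_raw: float
    d_jc: float
    kind: str  # "third_position" | "synonymous"

    @property
    def d_percent(self) -> float:
        return 100.0 * self.d_jc


def from_records(records: Iterable[tuple[str, str]], frame_offset: int = 0) -> CodonAlignment:
    """Build a CodonAlignment from (label, sequence) pairs."""
    taxa, seqs = [], []
    for label, seq in records:
        taxa.append(label)
        seqs.append(str(seq).upper())
    aln = CodonAlignment(tuple(taxa), tuple(seqs), frame_offset)
    dropped = aln.length_nt - aln.frame_offset - 3 * aln.n_codons
    if dropped:
        logger.warning("dropping %d nt of incomplete trailing codon", dropped)
    return aln


def read_codon_alignment(path, frame_offset: int = 0) -> CodonAlignment:
    """Read an in-frame codon alignment from a FASTA file."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if len(records) < 2:
        raise InputError(f"{path}: need at least 2 FASTA records, found {len(records)}")
    return from_records(records, frame_offset)


def jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise DomainError(f"proportion p={p} is negative")
    if p >= 0.75:
        raise SaturationError(p)
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def third_position_divergence(aln: CodonAlignment, a: str, b: str) -> DivergenceEstimate:
    """JC-corrected divergence over comparable third codon positions.

    Columns with a gap or ambiguous base in either sequence are excluded
    (pairwise deletion).
    """
    seq_a = aln.coding_region(a)
    seq_b = aln.coding_region(b)
    compared = 0
    diffs = 0
    for i in range(2, 3 * aln.n_codons, 3):
        x, y = seq_a[i], seq_b[i]
        if x in UNAMBIGUOUS and y in UNAMBIGUOUS:
            compared += 1
            if x != y:
                diffs += 1
    if compared == 0:
        raise DegenerateInputError(f"no comparable third-position sites for ({a!r}, {b!r})")
    p = diffs / compared
    return DivergenceEstimate((a, b), compared, p, jc_correct(p), "third_position")


def synonymous_divergence(aln: CodonAlignment, a: str, b: str) -> DivergenceEstimate:
    """NG86 synonymous-site divergence with JC correction.

    Codons with a gap or N in either sequence are skipped; in-frame stop
    codons are skipped with a warning (pseudogenes are expected input).
    sites_compared reports the number of codons that contributed counts.
    """
    s_sites = 0.0
    s_diff = 0.0
    codons_used = 0
    skipped_stops = 0
    for ca, cb in zip(aln.codons(a), aln.codons(b)):
        if not (ng86.is_resolved(ca) and ng86.is_resolved(cb)):
            continue
        if ng86.is_stop(ca) or ng86.is_stop(cb):
            skipped_stops += 1
            continue
        s, _n, sd, _nd = ng86.pair_codon_counts(ca, cb)
        s_sites += s
        s_diff += sd
        codons_used += 1
    if skipped_stops:
        logger.warning("skipped %d in-frame stop codons for (%s, %s)", skipped_stops, a, b)
    if s_sites == 0:
        raise DegenerateInputError(f"no synonymous sites for ({a!r}, {b!r})")
    p = s_diff / s_sites
    return DivergenceEstimate((a, b), codons_used, p, jc_correct(p), "synonymous")


def format_divergence(value: float | None) -> str:
    """Render a percent divergence the way the bundled tables print it."""
    if value is None:
        return "NA"
    if value < 0.1:
        return f"{value:.2g}"
    if value < 10:
        return f"{value:.2f}"
    return f"{value:.1f}"


def format_ratio(value: float | None) -> str:
    """Render a divergence ratio: <0.1 -> 3 dp, <10 -> 2 dp, else 1 dp."""
    if value is None or math.isnan(value):
        return "NA"
    if value < 0.1:
        return f"{value:.3f}"
    if value < 10:
        return f"{value:.2f}"
    return f"{value:.1f}"


@dataclass
class RatioRow:
    name: str
    divergences: dict[str, dict[str, float | None]]  # genome -> kind -> percent
    ratios: dict[tuple[str, str], dict[str, float | None]] = field(default_factory=dict)

    def ratio_str(self, num: str, den: str, kind: str) -> str:
        return format_ratio(self.ratios[(num, den)][kind])


@dataclass
class RatioTable:
    rows: dict[str, RatioRow]


def _ratio(num: float | None, den: float | None, context: str) -> float | None:
    if num is None or den is None:
        return None
    if den == 0:
        logger.warning("zero denominator for %s; ratio is NA", context)
        return None
    return num / den


def divergence_ratio_table(
    entries: Mapping[str, Mapping[str, Mapping[str, float | None]]],
) -> RatioTable:
    """Build the genome-divergence ratio table.

    ``entries`` maps pair name -> genome ("wolbachia"/"nuclear"/"mtdna") ->
    kind ("third"/"synonymous") -> percent divergence (None = NA).  Values
    may be computed estimates or printed percentages.
    """
    rows: dict[str, RatioRow] = {}
    for name, genomes in entries.items():
        div: dict[str, dict[str, float | None]] = {}
        for genome in GENOMES:
            kinds = genomes.get(genome, {})
            div[genome] = {
                "third": kinds.get("third"),
                "synonymous": kinds.get("synonymous"),
            }
        if div["wolbachia"]["third"] is None and div["wolbachia"]["synonymous"] is None:
            raise InputError(f"row {name!r} lacks a wolbachia divergence")
        row = RatioRow(name, div)
        for num, den in RATIOS:
            row.ratios[(num, den)] = {
                kind: _ratio(div[num][kind], div[den][kind], f"{name}:{num}/{den}:{kind}")
                for kind in ("third", "synonymous")
            }
        rows[name] = row
    return RatioTable(rows)
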