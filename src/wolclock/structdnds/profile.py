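"""Per-residue dN/dS from spherical windows on a reference structure.

NG86 per-codon quantities are indexed by reference residue, pooled within
each residue's spherical window, Jukes-Cantor corrected, and summarized as
the NA-aware median across pairwise comparisons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .. import ng86
from ..divergence import CodonAlignment, jc_correct
from ..exceptions import InputError, SaturationError

logger = logging.getLogger(__name__)

GAP_CHARS = set("-")


@dataclass
class SiteCounts:
    """NG86 quantities per reference codon for one pairwise comparison.

    Arrays are aligned with ``indices`` (reference residues 1..L); rows for
    codons that could not be counted (gap/N/stop in either sequence) are NaN.
    """

    comparison: str
    indices: np.ndarray
    s_sites: np.ndarray
    n_sites: np.ndarray
    s_diff: np.ndarray
    n_diff: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)


def pairwise_site_counts(aln: CodonAlignment, ref: str, other: str) -> SiteCounts:
    """NG86 counts at reference-ungapped codons, indexed 1..L.

    Codon columns where the reference carries a gap are dropped entirely, so
    counts line up with the reference protein's residues.  Codons that are
    unresolved in either sequence, or a stop in either, yield NaN rows.
    """
    ref_codons = aln.codons(ref)
    other_codons = aln.codons(other)
    idx, ss, ns, sd, nd = [], [], [], [], []
    residue = 0
    skipped_stops = 0
    for ca, cb in zip(ref_codons, other_codons):
        if any(c in GAP_CHARS for c in ca):
            continue  # no reference residue at this column
        residue += 1
        idx.append(residue)
        usable = (
            ng86.is_resolved(ca)
            and ng86.is_resolved(cb)
            and not ng86.is_stop(ca)
            and not ng86.is_stop(cb)
        )
        if not usable:
            if ng86.is_resolved(ca) and ng86.is_resolved(cb):
                skipped_stops += 1
            ss.append(np.nan), ns.append(np.nan), sd.append(np.nan), nd.append(np.nan)
            continue
        s, n, s_d, n_d = ng86.pair_codon_counts(ca, cb)
        ss.append(s), ns.append(n), sd.append(s_d), nd.append(n_d)
    if skipped_stops:
        logger.warning(
            "(%s, %s): %d in-frame stop codons excluded from counts", ref, other, skipped_stops
        )
    return SiteCounts(
        comparison=f"{ref}|{other}",
        indices=np.asarray(idx, dtype=int),
        s_sites=np.asarray(ss),
        n_sites=np.asarray(ns),
        s_diff=np.asarray(sd),
        n_diff=np.asarray(nd),
    )


def _pooled_omega(s_sites, n_sites, s_diff, n_diff) -> float:
    """dN/dS from pooled counts; NaN when undefined (dS = 0 or saturation)."""
    if not (s_sites > 0 and n_sites > 0):
        return np.nan
    try:
        dn = jc_correct(n_diff / n_sites)
        ds = jc_correct(s_diff / s_sites)
    except SaturationError as exc:
        logger.warning("window saturated (p=%.3f); omega set to NA", exc.p_raw)
        return np.nan
    if ds == 0:
        return np.nan
    return dn / ds


def window_omega(counts: SiteCounts, windows: dict[int, tuple[int, ...]]) -> np.ndarray:
    """Per-residue omega for one comparison by pooling counts over windows.

    ``windows`` maps residue index -> member residue indices (from
    ``spherical_windows``).  Residues absent from ``windows`` get NaN.
    """
    pos = {int(i): k for k, i in enumerate(counts.indices)}
    out = np.full(len(counts), np.nan)
    for k, i in enumerate(counts.indices):
        members = windows.get(int(i))
        if members is None:
            continue
        rows = [pos[m] for m in members if m in pos]
        if not rows:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            s = np.nansum(counts.s_sites[rows])
            n = np.nansum(counts.n_sites[rows])
            sd = np.nansum(counts.s_diff[rows])
            nd = np.nansum(counts.n_diff[rows])
        out[k] = _pooled_omega(s, n, sd, nd)
    return out


def global_omega(counts: SiteCounts) -> float:
    """Whole-protein NG86 omega (equivalent to an infinite-radius window)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return _pooled_omega(
            np.nansum(counts.s_sites),
            np.nansum(counts.n_sites),
            np.nansum(counts.s_diff),
            np.nansum(counts.n_diff),
        )


@dataclass
class SiteOmegaProfile:
    """Median per-residue omega across pairwise comparisons."""

    indices: np.ndarray
    per_comparison: np.ndarray  # shape (n_comparisons, L)
    comparisons: list[str]
    median: np.ndarray
    group_labels: list[str] = field(default_factory=list)
    flag: str = "intact"  # "intact" | "truncated"

    def to_dataframe(self) -> pd.DataFrame:
        labels = self.group_labels or ["none"] * len(self.indices)
        return pd.DataFrame(
            {
                "residue": self.indices,
                "group": labels,
                "median_omega": self.median,
                "n_comparisons": np.sum(~np.isnan(self.per_comparison), axis=0),
            }
        )


def median_profile(
    profiles: list[np.ndarray],
    indices: np.ndarray,
    comparisons: list[str] | None = None,
    group_labels: list[str] | None = None,
    flag: str = "intact",
) -> SiteOmegaProfile:
    """NA-aware per-residue median across comparisons.

    A residue is NA only when every comparison is NA there.
    """
    if not profiles:
        raise InputError("need at least one per-comparison profile")
    lengths = {len(p) for p in profiles} | {len(indices)}
    if len(lengths) != 1:
        raise InputError("profiles and indices disagree in length")
    stack = np.vstack(profiles)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(stack, axis=0)
    return SiteOmegaProfile(
        indices=np.asarray(indices),
        per_comparison=stack,
        comparisons=comparisons or [f"c{i}" for i in range(len(profiles))],
        median=med,
        group_labels=list(group_labels) if group_labels is not None else [],
        flag=flag,
    )


def label_residues(
    n_residues: int,
    domains: dict[str, list[tuple[int, int]]] | None = None,
    binding: list[tuple[int, int]] | None = None,
) -> list[str]:
    """Group labels per residue: 'domain:<name>' > 'binding' > 'none'.

    Ranges are inclusive 1-based (start, end) pairs.
    """
    labels = ["none"] * n_residues
    for start, end in binding or []:
        for i in range(start, min(end, n_residues) + 1):
            labels[i - 1] = "binding"
    for name, ranges in (domains or {}).items():
        for start, end in ranges:
            for i in range(start, min(end, n_residues) + 1):
                labels[i - 1] = f"domain:{name}"
    return labels
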