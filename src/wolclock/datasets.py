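"""Bundled calibration datasets.

Small TSV fixtures shipping with the package: pairwise genome divergences
for host systems with plausible cladogenic endosymbiont transmission, the
corresponding published ratio cells, and host divergence times with 95%
credible bounds.  These drive the rate calibration without any downloads.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .calibration import CladogenicPair, RateEstimate, rate_interval

CALIBRATION_WEIGHTS = {"nasonia": 1 / 3, "drosophila": 1 / 3, "nomada": 1 / 3}


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("wolclock.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", na_values=["NA"])


def load_divergence_table() -> pd.DataFrame:
    """Long-format divergence fixture: pair, genome, d_third, d_syn, bp."""
    return _read("cladogenic_divergence.tsv")


def divergence_entries() -> dict:
    """Fixture reshaped for :func:`wolclock.divergence.divergence_ratio_table`."""
    df = load_divergence_table()
    entries: dict = {}
    for row in df.itertuples():
        entries.setdefault(row.pair, {})[row.genome] = {
            "third": None if pd.isna(row.d_third) else float(row.d_third),
            "synonymous": None if pd.isna(row.d_syn) else float(row.d_syn),
        }
    return entries


def load_printed_ratios() -> pd.DataFrame:
    """Published ratio cells (as printed strings, 'NA' allowed)."""
    df = _read("printed_ratios.tsv")
    df["printed"] = df["printed"].fillna("NA").astype(str)
    return df


def load_calibration_pairs() -> list[CladogenicPair]:
    """Host pairs with divergences and host divergence times (+group tag)."""
    df = _read("calibration_pairs.tsv")
    pairs = []
    for row in df.itertuples():
        pairs.append(
            CladogenicPair(
                name=row.name,
                d_third_percent=float(row.d_third_percent),
                d_syn_percent=float(row.d_syn_percent),
                T_years=float(row.T_years),
                T_low=None if pd.isna(row.T_low) else float(row.T_low),
                T_high=None if pd.isna(row.T_high) else float(row.T_high),
            )
        )
    return pairs


def calibration_groups() -> dict[str, list[CladogenicPair]]:
    df = _read("calibration_pairs.tsv")
    pairs = load_calibration_pairs()
    groups: dict[str, list[CladogenicPair]] = {}
    for pair, group in zip(pairs, df["group"]):
        groups.setdefault(group, []).append(pair)
    return groups


def _pair_estimate(pair: CladogenicPair, basis: str) -> RateEstimate:
    d = pair.d_third_percent if basis == "third" else pair.d_syn_percent
    t_low = pair.T_low if pair.T_low is not None else pair.T_years
    t_high = pair.T_high if pair.T_high is not None else pair.T_years
    return rate_interval(d, pair.T_years, t_low, t_high, basis=basis, source=pair.name)


def reference_rate_estimates(basis: str = "third") -> dict[str, RateEstimate]:
    """One rate estimate per calibration example.

    Groups holding several host comparisons (the bee clade) are averaged
    into a single estimate, bounds included.
    """
    out = {}
    for group, pairs in calibration_groups().items():
        ests = [_pair_estimate(p, basis) for p in pairs]
        out[group] = RateEstimate(
            rate=float(np.mean([e.rate for e in ests])),
            rate_low=float(np.mean([e.rate_low for e in ests])),
            rate_high=float(np.mean([e.rate_high for e in ests])),
            basis=basis,
            source="+".join(p.name for p in pairs),
        )
    return out


def pooled_reference_rate(basis: str = "third") -> float:
    """Equal-weight mean rate over the calibration examples."""
    ests = reference_rate_estimates(basis)
    return float(np.mean([ests[g].rate for g in sorted(ests)]))
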