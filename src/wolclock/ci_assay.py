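"""Cytoplasmic-incompatibility hatch-rate analysis.

Pools per-day egg counts into per-cross hatch proportions over the assay
period, drops crosses that laid fewer than ``min_eggs`` eggs in total, and
tests whether incompatible (IC) crosses hatch fewer eggs than compatible
(CC) crosses with a one-sided rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateInputError, InputError, ValidationError

REQUIRED_COLUMNS = ("cross_id", "type", "day", "eggs", "hatched")
CROSS_TYPES = ("IC", "CC")
MAX_DAYS = 5


def validate_hatch_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the hatch-table invariants; returns the table unchanged."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"hatch table missing columns {missing}")
    if not table["type"].isin(CROSS_TYPES).all():
        bad = sorted(set(table["type"]) - set(CROSS_TYPES))
        raise ValidationError(f"unknown cross types {bad}")
    if (table["eggs"] < 0).any() or (table["hatched"] < 0).any():
        raise ValidationError("egg counts must be >= 0")
    if (table["hatched"] > table["eggs"]).any():
        raise ValidationError("hatched exceeds eggs laid in some rows")
    if not table["day"].between(1, MAX_DAYS).all():
        raise ValidationError(f"day must be in 1..{MAX_DAYS}")
    days_per_cross = table.groupby("cross_id")["day"].nunique()
    if (days_per_cross > MAX_DAYS).any():
        raise ValidationError(f"more than {MAX_DAYS} days recorded for a cross")
    return table


def pooled_hatch(table: pd.DataFrame, min_eggs: int = 10) -> pd.DataFrame:
    """Per-cross pooled hatch proportion over all days.

    Crosses with total eggs < ``min_eggs`` are removed (exactly ``min_eggs``
    is retained).  Returns columns cross_id, type, eggs, hatched, proportion.
    """
    validate_hatch_table(table)
    totals = (
        table.groupby(["cross_id", "type"], as_index=False)[["eggs", "hatched"]]
        .sum()
    )
    kept = totals[totals["eggs"] >= min_eggs].copy()
    if kept.empty:
        raise DegenerateInputError(f"all crosses laid fewer than {min_eggs} eggs")
    kept["proportion"] = kept["hatched"] / kept["eggs"]
    return kept.reset_index(drop=True)


def wilcoxon_one_sided(ic, cc, force_method: str | None = None) -> tuple[float, float]:
    """One-sided rank-sum test of IC stochastically smaller than CC.

    Exact null distribution when m + n <= 20 with no ties, otherwise the
    normal approximation with tie correction (mid-ranks).  Returns
    (U statistic, p).
    """
    ic = np.asarray(ic, dtype=float)
    cc = np.asarray(cc, dtype=float)
    if len(ic) == 0 or len(cc) == 0:
        raise InputError("both groups must be non-empty")
    pooled = np.concatenate([ic, cc])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if force_method is not None:
        method = force_method
    else:
        method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(ic, cc, alternative="less", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CiTestReport:
    n_ic: int
    n_cc: int
    mean_ic: float
    mean_cc: float
    sd_ic: float
    sd_cc: float
    statistic: float
    p_value: float
    min_eggs: int
    n_excluded: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def ci_test(table: pd.DataFrame, min_eggs: int = 10) -> CiTestReport:
    """Full pipeline: filter, pool, and test IC < CC."""
    n_crosses = table["cross_id"].nunique()
    pooled = pooled_hatch(table, min_eggs=min_eggs)
    ic = pooled.loc[pooled["type"] == "IC", "proportion"].to_numpy()
    cc = pooled.loc[pooled["type"] == "CC", "proportion"].to_numpy()
    if len(ic) == 0 or len(cc) == 0:
        raise DegenerateInputError("filtering removed an entire cross type")
    stat, p = wilcoxon_one_sided(ic, cc)
    return CiTestReport(
        n_ic=len(ic),
        n_cc=len(cc),
        mean_ic=float(ic.mean()),
        mean_cc=float(cc.mean()),
        sd_ic=float(ic.std(ddof=1)) if len(ic) > 1 else 0.0,
        sd_cc=float(cc.std(ddof=1)) if len(cc) > 1 else 0.0,
        statistic=stat,
        p_value=p,
        min_eggs=min_eggs,
        n_excluded=n_crosses - len(pooled),
    )
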