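"""Cladogenic co-divergence rate calibration and substitution-rate priors.

A host pair that co-diverged with its endosymbiont turns a printed pairwise
divergence and a host divergence time into a substitution rate:

    rate = (d_percent / 100) / (2 * T_years)

since pairwise divergence accrues along both lineages.  Credible bounds on
the host time map inversely onto the rate.  The module also exposes the
named rate priors (N1/U1/N2/U2 plus the legacy gamma-scaled prior) as
seeded samplers.

Rates are carried in substitutions/site/year throughout; any "x10^-9"
formatting belongs to the presentation layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, DomainError

MEAN_CALIBRATION_RATE = 1.65e-9  # pooled third-site rate shared by N1/U1/N2/U2
LEGACY_SCALE = 6.87e-9


@dataclass(frozen=True)
class CladogenicPair:
    """Printed divergences plus a host divergence time with credible bounds."""

    name: str
    d_third_percent: float
    T_years: float
    d_syn_percent: float | None = None
    T_low: float | None = None
    T_high: float | None = None

    def __post_init__(self):
        if self.d_third_percent < 0:
            raise DomainError("divergence must be >= 0")
        if self.T_low is not None and self.T_high is not None:
            if not (self.T_low <= self.T_years <= self.T_high):
                raise DomainError(
                    f"{self.name}: require T_low <= T <= T_high, got "
                    f"({self.T_low}, {self.T_years}, {self.T_high})"
                )


@dataclass(frozen=True)
class RateEstimate:
    rate: float
    rate_low: float
    rate_high: float
    basis: str  # "third" | "synonymous"
    source: str

    def __post_init__(self):
        if not (self.rate_low <= self.rate <= self.rate_high):
            raise DomainError("rate bounds must bracket the point estimate")


@dataclass(frozen=True)
class PriorComponent:
    weight: float
    family: str  # "normal" | "uniform" | "gamma"
    params: tuple[float, float]
    scale: float


@dataclass(frozen=True)
class PriorSpec:
    name: str
    components: tuple[PriorComponent, ...] = field(default_factory=tuple)

    def __post_init__(self):
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"prior {self.name}: component weights sum to {total}, not 1")

    @property
    def mean(self) -> float:
        """Analytic mean of the (untruncated) mixture."""
        out = 0.0
        for c in self.components:
            a, b = c.params
            if c.family == "normal":
                m = a
            elif c.family == "uniform":
                m = (a + b) / 2.0
            elif c.family == "gamma":
                m = a / b
            else:  # pragma: no cover
                raise ConfigError(f"unknown family {c.family!r}")
            out += c.weight * m * c.scale
        return out


def cladogenic_rate(d_percent: float, T_years: float) -> float:
    """Substitutions/site/year from a pairwise divergence and split time."""
    if d_percent < 0:
        raise DomainError(f"divergence {d_percent} must be >= 0")
    if T_years <= 0:
        raise DomainError(f"divergence time {T_years} must be > 0")
    return (d_percent / 100.0) / (2.0 * T_years)


def rate_interval(
    d_percent: float,
    T_years: float,
    T_low: float,
    T_high: float,
    basis: str = "third",
    source: str = "",
) -> RateEstimate:
    """Rate with 95% bounds propagated from host-time credible bounds.

    The mapping T -> rate is inverse-monotone, so the lower rate bound comes
    from the upper time bound and vice versa.
    """
    if not (0 < T_low <= T_years <= T_high):
        raise DomainError(
            f"require 0 < T_low <= T <= T_high, got ({T_low}, {T_years}, {T_high})"
        )
    return RateEstimate(
        rate=cladogenic_rate(d_percent, T_years),
        rate_low=cladogenic_rate(d_percent, T_high),
        rate_high=cladogenic_rate(d_percent, T_low),
        basis=basis,
        source=source,
    )


def pooled_rate(estimates, weights) -> float:
    """Weighted arithmetic mean of rate estimates."""
    estimates = list(estimates)
    weights = list(weights)
    if len(estimates) != len(weights):
        raise DomainError("estimates and weights differ in length")
    if any(w < 0 for w in weights):
        raise DomainError("weights must be >= 0")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise DomainError(f"weights sum to {sum(weights)}, not 1")
    return float(sum(w * r for w, r in zip(weights, estimates)))


_PRIORS: dict[str, tuple[PriorComponent, ...]] = {
    "N1": (PriorComponent(1.0, "normal", (1.0, 0.34), MEAN_CALIBRATION_RATE),),
    "U1": (PriorComponent(1.0, "uniform", (0.33, 1.67), MEAN_CALIBRATION_RATE),),
    "N2": (
        PriorComponent(1 / 3, "normal", (1.0, 0.36), 0.56e-9),
        PriorComponent(2 / 3, "normal", (1.0, 0.08), 2.2e-9),
    ),
    "U2": (
        PriorComponent(1 / 3, "uniform", (0.3, 1.7), 0.56e-9),
        PriorComponent(2 / 3, "uniform", (0.84, 1.16), 2.2e-9),
    ),
    "legacy": (PriorComponent(1.0, "gamma", (7.0, 7.0), LEGACY_SCALE),),
}


def make_prior(name: str) -> PriorSpec:
    """Named substitution-rate prior.

    N1/U1/N2/U2 all have mean 1.65e-9 substitutions/third-site/year; the
    legacy prior is Gamma(7, 7) scaled by 6.87e-9.
    """
    try:
        components = _PRIORS[name]
    except KeyError:
        raise ConfigError(
            f"unknown prior {name!r}; choose from {sorted(_PRIORS)}"
        ) from None
    return PriorSpec(name, components)


def point_mass_prior(rate: float) -> PriorSpec:
    """Degenerate prior concentrated at a single rate (testing/scaling)."""
    if rate <= 0:
        raise DomainError("rate must be positive")
    return PriorSpec("point", (PriorComponent(1.0, "uniform", (1.0, 1.0), rate),))


def sample_prior(
    prior: PriorSpec,
    n: int,
    seed: int | np.random.Generator,
    positive_only: bool = False,
) -> np.ndarray:
    """Draw ``n`` rates from a prior, reproducibly.

    ``positive_only=True`` rejects and redraws non-positive values (used when
    the draws feed an age scaling, where a negative rate is meaningless).
    The default is the literal prior, whose normal components carry a tiny
    amount of mass below zero.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights = np.array([c.weight for c in prior.components])
    choice = rng.choice(len(prior.components), size=n, p=weights)
    draws = np.empty(n, dtype=float)
    for idx, comp in enumerate(prior.components):
        mask = choice == idx
        m = int(mask.sum())
        if m == 0:
            continue
        a, b = comp.params
        if comp.family == "normal":
            vals = rng.normal(a, b, size=m)
            if positive_only:
                bad = vals <= 0
                while bad.any():
                    vals[bad] = rng.normal(a, b, size=int(bad.sum()))
                    bad = vals <= 0
        elif comp.family == "uniform":
            vals = rng.uniform(a, b, size=m) if a < b else np.full(m, a)
        elif comp.family == "gamma":
            vals = rng.gamma(shape=a, scale=1.0 / b, size=m)
        else:  # pragma: no cover
            raise ConfigError(f"unknown family {comp.family!r}")
        draws[mask] = vals * comp.scale
    return draws


def format_rate(rate: float) -> str:
    """Human-readable 'x10^-9' presentation of a rate."""
    if rate == 0:
        return "0"
    exponent = -9
    mantissa = rate / 10.0**exponent
    return f"{mantissa:.2g}x10^{exponent}"


def two_sig_figs(x: float) -> float:
    """Round to two significant figures (report formatting helper)."""
    if x == 0:
        return 0.0
    magnitude = math.floor(math.log10(abs(x)))
    return round(x, -magnitude + 1)
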