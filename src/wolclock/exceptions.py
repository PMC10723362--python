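"""Exception hierarchy shared by all wolclock modules."""


class WolclockError(Exception):
    """Base class for all package-specific errors."""


class FormatError(WolclockError, ValueError):
    """Malformed input file (bad FASTA, non-IUPAC characters, ...)."""


class InputError(WolclockError, ValueError):
    """Structurally valid input that violates an operation precondition."""


class DomainError(WolclockError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class SaturationError(DomainError):
    """Raw divergence at or beyond the Jukes-Cantor singularity (p >= 0.75)."""

    def __init__(self, p_raw: float, message: str | None = None):
        self.p_raw = p_raw
        super().__init__(message or f"raw divergence p={p_raw:.4f} is saturated (>= 0.75)")


class DegenerateInputError(InputError):
    """No usable sites/observations remain after filtering."""


class ValidationError(WolclockError, ValueError):
    """Data object violates a declared invariant."""


class ConfigError(WolclockError, ValueError):
    """Unknown name or inconsistent configuration."""
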