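"""Exception hierarchy shared across the package."""


class MicroviError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MicroviError, ValueError):
    """An argument is outside its documented domain."""


class FormatError(MicroviError, ValueError):
    """An input file does not conform to the expected plain-text format."""


class AlignmentError(MicroviError, ValueError):
    """Sample (or taxon) identifiers do not line up across input tables."""


class ValidationError(MicroviError, ValueError):
    """Data violate a structural invariant (negative counts, unknown level, ...)."""


class DimensionError(MicroviError, ValueError):
    """Array shapes do not conform."""


class DomainError(MicroviError, ValueError):
    """A value lies outside the mathematical domain of a density."""


class NumericError(MicroviError, ArithmeticError):
    """A non-finite value appeared where a finite one is required."""


class OptimizationError(MicroviError, RuntimeError):
    """Stochastic optimization diverged (ELBO became non-finite)."""


class ScenarioError(MicroviError, ValueError):
    """A synthetic-data scenario produced numerically unusable settings."""
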