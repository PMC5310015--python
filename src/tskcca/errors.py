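"""Exception hierarchy for tskcca.

All package errors derive from :class:`TskccaError` so callers can catch a
single base class at pipeline boundaries.
"""


class TskccaError(Exception):
    """Base class for all tskcca errors."""


class InvalidInputError(TskccaError, ValueError):
    """Malformed, non-finite, or dimensionally inconsistent input."""


class DegenerateBankError(TskccaError):
    """A sub-kernel bank became empty (e.g. every kernel had zero variance)."""


class DegenerateVectorError(TskccaError):
    """An all-zero vector where a nonzero one is required."""


class ConvergenceError(TskccaError):
    """Alternating optimization failed to produce a usable iterate."""


class ConditioningError(TskccaError):
    """A regularized matrix was numerically singular."""


class UndefinedCorrelationError(TskccaError):
    """Pearson correlation requested for a zero-variance score vector."""
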