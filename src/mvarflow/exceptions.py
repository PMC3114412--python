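"""Exception hierarchy for mvarflow.

All errors raised deliberately by the library derive from :class:`MvarflowError`
so callers can catch the whole family; each also derives from the closest
builtin (ValueError / ArithmeticError) so untyped callers get sensible
behaviour.
"""


class MvarflowError(Exception):
    """Base class for all mvarflow errors."""


class InvalidArgumentError(MvarflowError, ValueError):
    """An argument is outside its documented domain."""


class DegenerateDataError(MvarflowError, ValueError):
    """Data is degenerate for the requested operation (e.g. zero variance)."""


class UnderdeterminedModelError(MvarflowError, ValueError):
    """Too few regression rows to fit the requested model order."""


class SingularityError(MvarflowError, ArithmeticError):
    """A matrix that must be inverted is singular at a specific frequency."""


class ConditioningError(MvarflowError, ArithmeticError):
    """A matrix is too ill-conditioned to invert reliably."""
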