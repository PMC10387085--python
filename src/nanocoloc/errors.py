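"""Exception hierarchy for the nanocoloc pipeline.

Validation problems (bad shapes, out-of-range parameters, inconsistent
condition labels) raise :class:`ValidationError`.  Statistics that are
mathematically undefined on the given input (e.g. Pearson correlation of a
constant channel) raise :class:`UndefinedStatisticError` so callers can
distinguish "you passed garbage" from "this quantity does not exist here".
"""


class NanocolocError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NanocolocError, ValueError):
    """Input violates a precondition (shape, range, consistency)."""


class UndefinedStatisticError(NanocolocError, ArithmeticError):
    """The requested statistic is undefined for this input (e.g. constant
    channel, all-zero channel, non-positive denominator)."""


class InsufficientDataError(NanocolocError, ValueError):
    """Too few observations to compute the requested summary."""


class PlacementError(NanocolocError, RuntimeError):
    """Cell placement failed after the retry budget was exhausted."""
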