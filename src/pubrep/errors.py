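"""Exception hierarchy for pubrep.

All data-level problems derive from :class:`PubrepError` so that callers
(and the CLI) can distinguish bad input from genuine bugs.
"""


class PubrepError(Exception):
    """Base class for all pubrep-specific errors."""


class InvalidInputError(PubrepError, ValueError):
    """An argument violates a documented precondition."""


class EmptyRepertoireError(InvalidInputError):
    """An operation requires at least one cell (N >= 1)."""


class ConfigurationError(PubrepError):
    """A required piece of configuration (e.g. sample sizes) is missing."""


class ResourceGuardError(PubrepError):
    """An O(Omega^2) pair sum was requested above the guard limit.

    Pair sums over all ordered clone pairs grow quadratically with the
    number of clone slots.  Beyond ``PAIR_SUM_LIMIT`` clones the caller
    must opt in explicitly by passing a ``chunk_size``; silently starting
    a multi-hour computation is worse than an explicit switch.
    """


class NumericalConsistencyError(PubrepError):
    """A probability left [0, 1] by more than the clamping tolerance."""


class UnsupportedBranchError(PubrepError, ValueError):
    """A closed-form branch is not defined at the requested exponent."""
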