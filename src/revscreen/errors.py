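"""Exception hierarchy shared across the pipeline.

All pipeline-raised errors derive from :class:`RevScreenError` so callers
(and the CLI) can distinguish user/data problems from genuine bugs.
"""


class RevScreenError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(RevScreenError):
    """A file does not conform to the expected table/GMT layout."""


class ValidationError(RevScreenError):
    """Input values violate a documented precondition or invariant."""


class OverlapError(RevScreenError):
    """Two gene collections share too few genes for the requested statistic."""


class UndefinedStatisticError(RevScreenError):
    """A statistic is undefined for the given input (e.g. constant ranks)."""
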