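"""Exception hierarchy for the pipeline.

Validation problems (bad arguments, bad config) and data problems (bad
files, degenerate inputs) are kept distinct so the CLI can map them to
different exit codes.
"""


class NirsPlvError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(NirsPlvError, ValueError):
    """An argument violates an operation's precondition."""


class ConfigValidationError(NirsPlvError, ValueError):
    """A run configuration failed validation before any computation."""


class FormatError(NirsPlvError):
    """A file does not parse under the named standard; names the offending field."""


class LayoutError(NirsPlvError):
    """Channel count or labels disagree with the probe layout."""


class DataError(NirsPlvError):
    """Data values violate an invariant (e.g. non-positive intensity)."""


class SegmentLengthError(InvalidArgumentError):
    """A continuous segment is too short for stable phase estimation."""


class DegenerateInputError(DataError):
    """A statistical input with no usable variability (e.g. < 2 pairs)."""


class EmptyEpochSetError(DataError):
    """Epoching produced no valid epochs."""
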