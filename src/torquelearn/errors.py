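"""Exception hierarchy for the torquelearn pipeline.

Distinct error kinds are deliberate: file-level problems (malformed XML,
missing trace, schedule/trace mismatch) must be distinguishable by callers
that batch-process whole datasets and report per-fly failures.
"""


class TorquelearnError(Exception):
    """Base class for all package errors."""


class ValidationError(TorquelearnError):
    """A domain object violates one of its invariants."""


class MalformedFileError(TorquelearnError):
    """A raw experiment or descriptor file could not be parsed."""


class MissingTraceError(MalformedFileError):
    """A raw experiment file contains no time-series data."""


class ScheduleMismatchError(ValidationError):
    """Trace duration does not cover the period schedule."""


class UnknownProtocolError(TorquelearnError):
    """A protocol (setup) name is not recognised."""


class UnsupportedProtocolError(TorquelearnError):
    """The requested operation does not apply to this protocol.

    Raised e.g. when optomotor analysis is requested for a Tang-setup
    record, whose device never stored optomotor traces.
    """


class UndefinedPIError(TorquelearnError):
    """Performance index undefined: the fly never flew in the period."""


class UndefinedIndexError(TorquelearnError):
    """Asymmetry index undefined: both optomotor magnitudes are zero."""


class DegenerateSampleError(TorquelearnError):
    """A statistical test received a degenerate sample (e.g. all zeros)."""


class EmptyGroupError(TorquelearnError):
    """A dataset group has no included flies after quality control."""
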