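"""Exception hierarchy for eegpress.

All package errors derive from :class:`EEGPressError` so callers can catch
one base class; subclasses distinguish format, parameter, data and codec
failures.
"""


class EEGPressError(Exception):
    """Base class for all eegpress errors."""


class FormatError(EEGPressError):
    """A file does not parse as the format it claims to be."""


class UnsupportedFormatError(FormatError):
    """The file is a valid but unsupported dialect (e.g. discontinuous EDF+D,
    or mixed per-channel sampling rates)."""


class ParameterError(EEGPressError, ValueError):
    """An argument is outside its documented domain."""


class DataError(EEGPressError):
    """Input data violate a precondition (non-finite samples, empty signal)."""


class ShapeError(EEGPressError):
    """Inconsistent array shapes between objects that must agree."""


class InfeasibleTargetError(EEGPressError):
    """The requested compression ratio cannot be reached even at zero
    retained coefficients (the serialized payload has a fixed floor)."""


class IterationError(EEGPressError):
    """The rate-control search failed to converge.

    The best iterate found is attached as ``best``.
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class CorruptArchiveError(EEGPressError):
    """A compressed epoch block failed its checksum or is truncated."""

    def __init__(self, message, epoch_index=None):
        super().__init__(message)
        self.epoch_index = epoch_index


class SchemaError(EEGPressError):
    """A concordance penalty schema violates a structural rule."""


class ScoringError(EEGPressError):
    """A score record is missing or mistypes a required response."""


class UndefinedMetricError(EEGPressError):
    """A metric is undefined for the given input (e.g. PRD of a zero signal)."""
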