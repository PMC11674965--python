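"""Exception hierarchy for streamconn.

All package errors derive from :class:`StreamConnError`; the CLI maps them to
exit code 1 (validation) while unexpected exceptions map to exit code 2.
"""


class StreamConnError(Exception):
    """Base class for all streamconn errors."""


class ValidationError(StreamConnError):
    """Invalid configuration or malformed input table."""


class StationarityError(ValidationError):
    """A VAR system has companion spectral radius >= 1."""


class DegenerateSignalError(ValidationError):
    """A signal is constant (or otherwise cannot be normalized/correlated)."""


class SizingError(ValidationError):
    """Too few samples/subjects for the requested operation."""


class StructuralError(ValidationError):
    """A required ROI, column or file is missing."""


class ConditioningError(StreamConnError):
    """Near-singular regressor matrix in least-squares VAR estimation."""
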