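"""Exception hierarchy shared across the pipeline stages."""


class Ecg2BpError(Exception):
    """Base class for all package errors."""


class FormatError(Ecg2BpError):
    """A record file is malformed (ragged channels, non-numeric samples, bad header)."""


class RangeError(Ecg2BpError):
    """A time/sample interval lies outside the record."""


class ParameterError(Ecg2BpError):
    """A numeric parameter violates a precondition (e.g. fs <= 2*cutoff)."""


class AlignmentError(Ecg2BpError):
    """Paired sequences disagree in length."""


class SchemaError(Ecg2BpError):
    """A required channel or field is missing."""


class ConfigError(Ecg2BpError):
    """An invalid configuration (cross-field invariant violated)."""


class DataError(Ecg2BpError):
    """No usable data for the requested operation (empty split, no valid labels)."""


class InsufficientDataError(DataError):
    """Fewer samples/beats than the operation needs."""


class DivergenceError(Ecg2BpError):
    """Training produced a non-finite loss."""


class ShapeError(Ecg2BpError):
    """An array has the wrong shape for the model."""


class ModelPersistenceError(Ecg2BpError):
    """A model directory is missing, corrupt, or incompatible."""


class UndefinedCorrelationError(Ecg2BpError):
    """Correlation requested on a zero-variance sequence."""
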