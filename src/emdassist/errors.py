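"""Exception types raised by the emdassist pipeline."""


class EmdAssistError(ValueError):
    """Base class for all package-specific errors."""


class ParameterError(EmdAssistError):
    """An invalid configuration or generator parameter."""


class InputError(EmdAssistError):
    """Malformed or degenerate input data (empty windows, short series...)."""


class GeometryError(EmdAssistError):
    """Marker geometry is degenerate (e.g. coincident wrist and elbow)."""


class NormalizationError(EmdAssistError):
    """Control-condition reference for EMG normalization is unusable."""


class OnsetOrderingError(EmdAssistError):
    """Detected EMG onset does not follow the cue."""


class DegenerateDataError(EmdAssistError):
    """Outcome data carry no variance; the mixed model cannot be fit."""


class SchemaError(EmdAssistError):
    """An on-disk dataset does not conform to the expected layout."""
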