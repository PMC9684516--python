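"""Exception types shared across the package."""


class DeltaRadError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DeltaRadError, ValueError):
    """Raised when a configuration object violates its invariants."""


class VolumeIOError(DeltaRadError, OSError):
    """Raised when a volume file cannot be read or written."""


class DegenerateROIError(DeltaRadError, ValueError):
    """Raised when an ROI is too small or uniform for the requested operation."""


class ModelingError(DeltaRadError, ValueError):
    """Raised when a model cannot be fit (e.g. single-class labels)."""
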