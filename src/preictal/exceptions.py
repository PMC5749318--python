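"""Exception hierarchy for the preictal package."""


class PreictalError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PreictalError, ValueError):
    """Invalid configuration (durations, onsets, horizons, ...)."""


class FormatError(PreictalError, ValueError):
    """Malformed or unsupported file content."""


class UnsupportedFormatError(FormatError):
    """A file is structurally valid but uses features we reject (e.g. mixed rates)."""


class DegenerateSignalError(PreictalError, ValueError):
    """A signal has no usable structure (zero energy, too few samples, ...)."""


class SiftFailure(PreictalError, RuntimeError):
    """Sifting could not proceed (insufficient extrema)."""
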