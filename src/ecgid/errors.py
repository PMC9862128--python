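"""Exception hierarchy for the ecgid package."""


class EcgIdError(Exception):
    """Base class for all ecgid errors."""


class InputFormatError(EcgIdError):
    """A file or stream could not be parsed; the message names the offending field."""


class ValidationError(EcgIdError):
    """Data violates a documented invariant (non-finite samples, label mismatch, ...)."""


class DegenerateInputError(ValidationError):
    """Input is structurally valid but degenerate for the operation (e.g. constant series)."""


class ConfigurationError(EcgIdError):
    """A configuration value is out of range or inconsistent (e.g. cutoff above Nyquist)."""
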