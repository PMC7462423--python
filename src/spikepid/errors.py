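"""Exception types shared across the package."""


class SpikePIDError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SpikePIDError, ValueError):
    """Input violates a documented precondition."""


class SpikeTableParseError(SpikePIDError, ValueError):
    """A spike-table file could not be parsed; carries the offending line."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ConfigurationError(SpikePIDError, ValueError):
    """Analysis settings are internally inconsistent (e.g. too few surrogates
    to resolve the requested significance level)."""


class ConsistencyError(SpikePIDError, RuntimeError):
    """An internal identity that must hold to numerical precision failed."""
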