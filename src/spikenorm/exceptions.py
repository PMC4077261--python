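"""Exception hierarchy shared across the package."""


class SpikenormError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SpikenormError, ValueError):
    """A file does not conform to the expected dialect (missing column,
    duplicate identifier, malformed section)."""


class ParseError(FormatError):
    """A value could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class AlignmentError(FormatError):
    """Probe rosters differ between files that must share one."""

    def __init__(self, message: str, probes=()):
        super().__init__(message)
        self.probes = list(probes)


class AnnotationError(FormatError):
    """A probe present in the data is missing from the annotation table."""


class ConfigurationError(SpikenormError, ValueError):
    """Invalid or insufficient configuration for the requested operation
    (e.g. fewer than two spike-in probe sets for SCN)."""


class FallbackRequired(ConfigurationError):
    """Raised when a correction function cannot be built and the caller
    should fall back to MEDIAN normalization."""
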