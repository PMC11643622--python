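"""Exception types shared across the package."""


class VrcallError(Exception):
    """Base class for all package-specific errors."""


class FormatError(VrcallError):
    """Raised when an input file does not conform to its declared format."""


class ValidationError(VrcallError):
    """Raised when data violate a domain invariant (duplicates, negative counts, ...)."""


class ConfigurationError(VrcallError):
    """Raised when a required gene, column, or parameter is missing or inconsistent."""
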