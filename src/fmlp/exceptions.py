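"""Exception hierarchy shared across the package."""


class FmlpError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FmlpError, ValueError):
    """Raised when an input violates an operation's contract."""


class InvalidSpecError(ValidationError):
    """Raised when a shape specification cannot produce a valid mask."""


class DegenerateDataError(ValidationError):
    """Raised when data cannot support the requested computation
    (e.g. fewer distinct points than clusters)."""


class NoBorderError(FmlpError):
    """Raised when no closed border component can be found in an image."""
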