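"""Exception types shared across the package."""


class CalciscopeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CalciscopeError, ValueError):
    """An argument or data structure violates a documented precondition."""


class ImageFormatError(CalciscopeError, ValueError):
    """A file decodes, but not into the layout the caller declared."""
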