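"""Exception types shared across the package."""


class XgbcdaError(Exception):
    """Base class for all package errors."""


class ParseError(XgbcdaError):
    """A file could not be parsed; the message names the offending location."""


class ValidationError(XgbcdaError):
    """An input violated a documented precondition or invariant."""
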