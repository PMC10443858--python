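"""Exception hierarchy shared across the package."""


class Eye3DError(Exception):
    """Base class for all package errors."""


class InputError(Eye3DError):
    """A file or path could not be read."""


class ValidationError(Eye3DError):
    """An argument violates an operation's contract."""
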