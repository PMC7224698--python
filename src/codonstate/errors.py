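"""Exception types shared across the package."""


class CodonstateError(Exception):
    """Base class for package errors."""


class ValidationError(CodonstateError, ValueError):
    """An input record or parameter violates a documented invariant."""


class MissingInputError(CodonstateError, FileNotFoundError):
    """A required input file or table is absent."""
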