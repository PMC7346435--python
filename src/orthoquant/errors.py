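"""Exception types shared across the package."""


class OrthoquantError(Exception):
    """Base class for all package errors."""


class ParseError(OrthoquantError, ValueError):
    """A file could not be parsed (malformed header, wrong field count, ...)."""


class ValidationError(OrthoquantError, ValueError):
    """Parsed content violates a documented invariant (negative TPM, duplicate
    gene ID, confidence outside {0,1}, degenerate inputs, ...)."""
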