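"""Exception hierarchy.

All user-facing failures derive from :class:`VennKitError` so the CLI can
catch one type, print one diagnostic line, and exit non-zero.
"""


class VennKitError(Exception):
    """Base class for all errors raised by vennkit."""


class CapacityError(VennKitError):
    """More than six sets requested; the diagram family stops at n=6."""


class ValidationError(VennKitError):
    """Invalid value for an otherwise well-formed input."""


class ParseError(VennKitError):
    """Syntax error in a tree, union-code or union-list expression.

    ``position`` is a 0-based character offset into the parsed text when
    known, else ``None``.
    """

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class FormatError(VennKitError):
    """Malformed sets file.  ``line`` is the 1-based offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class CapabilityUnavailableError(VennKitError):
    """An optional capability (PNG rasterization) has no available backend."""
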