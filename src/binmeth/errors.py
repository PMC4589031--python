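"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: configuration problems exit 2, data
problems (parse/validation/undefined results) exit 3.
"""


class BinmethError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BinmethError):
    """Invalid or inconsistent run configuration (exit code 2)."""


class ValidationError(BinmethError):
    """Input violates a documented contract."""


class ParseError(ValidationError):
    """Malformed input line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class UndefinedResultError(BinmethError):
    """A quantity is requested for which no defined value exists
    (e.g. the mean of an empty set of passing bins)."""
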