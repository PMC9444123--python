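"""Exception hierarchy.

The CLI maps these onto exit codes: validation problems exit 1, I/O
problems exit 2, anything else exit 3.
"""


class AnodetError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(AnodetError, ValueError):
    """An argument, configuration or data structure violates a contract."""


class ParseError(ValidationError):
    """An input file is syntactically malformed.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SchemaError(ValidationError):
    """An input file parses but is internally inconsistent."""
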