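"""Exception hierarchy shared across the package.

Validation errors signal a contract violation in the caller's data or
configuration (CLI exit code 2); parse errors additionally carry the
offending line number of a tabular input file.
"""


class LeadnetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LeadnetError, ValueError):
    """Input data or configuration violates a documented precondition."""


class ParseError(LeadnetError, ValueError):
    """A tabular input file could not be parsed.

    Parameters
    ----------
    message : str
        Human-readable description.
    line : int, optional
        1-based line number of the offending row.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
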