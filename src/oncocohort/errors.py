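"""Exception hierarchy shared by all readers, writers and pipeline stages."""


class OncocohortError(Exception):
    """Base class for all toolkit errors."""


class ParseError(OncocohortError):
    """A line of an input file could not be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SchemaError(OncocohortError):
    """A tabular input is missing required columns."""


class ValidationError(OncocohortError):
    """A record violates a domain invariant (bad enum value, duplicate name, ...)."""


class PreconditionError(OncocohortError):
    """An operation was called with arguments outside its contract."""


class DesignError(OncocohortError):
    """A synthetic-cohort design is internally inconsistent or infeasible."""
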