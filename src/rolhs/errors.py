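"""Exception hierarchy shared across modules."""


class RolhsError(Exception):
    """Base class for all package errors."""


class MalformedFileError(RolhsError):
    """A file failed to parse; carries the offending line when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class IntegrityError(RolhsError):
    """Structural invariant violated (dangling parent, cycle, ...)."""

    def __init__(self, message: str, codes: set[str] | None = None):
        self.codes = set(codes or ())
        super().__init__(message)


class LookupFailure(RolhsError, KeyError):
    """An identifier was not found where the contract requires it."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return Exception.__str__(self)


class ArgumentFailure(RolhsError, ValueError):
    """An argument violates a precondition."""


class MappingFailure(RolhsError):
    """Relational->RDF mapping could not be compiled."""


class ConfigurationFailure(RolhsError):
    """Rules or specs reference schema elements that do not exist."""


class UndefinedMetricFailure(RolhsError):
    """A metric is undefined for the given input (zero vector, empty mask...)."""
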