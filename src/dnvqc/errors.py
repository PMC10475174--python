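"""Exception and warning types shared across dnvqc."""


class DnvqcError(Exception):
    """Base class for all dnvqc domain errors."""


class ConfigurationError(DnvqcError):
    """A required column, parameter, or resource is missing or unusable."""


class ParseError(DnvqcError):
    """A file could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ValidationError(DnvqcError, ValueError):
    """A value violates a record invariant (bad allele, position, ...)."""


class ContractError(DnvqcError):
    """An operation was called outside its precondition."""


class DNVWarning(UserWarning):
    """Non-fatal issue worth surfacing in QC reports."""
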