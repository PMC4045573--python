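"""Exception types shared across the package."""


class KeynodesError(Exception):
    """Base class for all package-specific errors."""


class ParseError(KeynodesError, ValueError):
    """A network file could not be parsed.

    Carries the offending line number when it is known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(KeynodesError, ValueError):
    """A network violates a structural invariant (self-loop, bad conductance, ...)."""


class SolverError(KeynodesError, RuntimeError):
    """A circuit solve failed (non-convergence, invalid source/target, ...)."""
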