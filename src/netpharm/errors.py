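"""Exception hierarchy shared across the package."""


class NetpharmError(Exception):
    """Base class for all package-specific errors."""


class ParseError(NetpharmError, ValueError):
    """A malformed line in an input file; carries the 1-based line number."""

    def __init__(self, path, lineno, message):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{self.path}:{lineno}: {message}")


class ValidationError(NetpharmError, ValueError):
    """Input violates a documented precondition or invariant."""


class UsageError(NetpharmError, ValueError):
    """Bad argument value (unknown format token, fraction out of range...)."""


class ConvergenceError(NetpharmError, ArithmeticError):
    """An iterative numerical routine failed to reach tolerance."""

    def __init__(self, message, residual=None):
        self.residual = residual
        super().__init__(message)


class PipelineError(NetpharmError, RuntimeError):
    """A pipeline stage failed; names the stage."""

    def __init__(self, stage, cause):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
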