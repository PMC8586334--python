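"""Exception and warning types shared across the package."""

__all__ = [
    "UnwindkitError",
    "InputError",
    "DegenerateForceError",
    "ConvergenceError",
    "EmptyResultError",
    "ConfigError",
    "ParseError",
    "ExtrapolationWarning",
    "SlopeSignWarning",
    "OverfitWarning",
]


class UnwindkitError(Exception):
    """Base class for package errors."""


class InputError(UnwindkitError, ValueError):
    """Invalid argument or malformed input data."""


class DegenerateForceError(UnwindkitError):
    """The per-bp extension signal vanishes at the given force."""


class ConvergenceError(UnwindkitError):
    """An iterative fit failed to converge."""


class EmptyResultError(UnwindkitError):
    """A filter or selection left nothing to summarize."""


class ConfigError(UnwindkitError, ValueError):
    """Run configuration failed schema validation."""


class ParseError(UnwindkitError, ValueError):
    """A data file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ExtrapolationWarning(UserWarning):
    """A fitted quantity lies outside the sampled data range."""


class SlopeSignWarning(UserWarning):
    """A fitted slope has an unexpected sign."""


class OverfitWarning(UserWarning):
    """A parameter choice is expected to overfit (e.g. zero penalty)."""
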