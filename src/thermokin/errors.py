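"""Exception hierarchy shared across the package."""


class ThermokinError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ThermokinError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(ThermokinError, ValueError):
    """A file does not conform to the expected on-disk format.

    Carries the 1-based line number of the first offending line when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class DegenerateFitError(ThermokinError, RuntimeError):
    """A regression problem is degenerate (rank deficient or zero signal)."""


class FitWarning(UserWarning):
    """Non-fatal issue during fitting, e.g. an all-censored delay regression."""
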