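"""Exception and warning types shared across the package."""


class MFReleaseError(Exception):
    """Base class for all package errors."""


class ParameterError(MFReleaseError):
    """A model parameter is missing or malformed."""


class DomainError(MFReleaseError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class InsufficientDataError(MFReleaseError):
    """Too few usable points to perform a fit or transform."""


class FitError(MFReleaseError):
    """A least-squares fit failed (degenerate design or non-convergence).

    May carry a ``fallback`` attribute holding a linearized fit when the
    nonlinear route failed after a successful linearized one.
    """

    def __init__(self, message, fallback=None):
        super().__init__(message)
        self.fallback = fallback


class ParseError(MFReleaseError):
    """A data file could not be parsed; message names the offending row."""


class StabilityError(MFReleaseError):
    """A numerical scheme violated its stability contract."""


class ExhaustionWarning(UserWarning):
    """The cube-root (Hixson-Crowell) law drove the remaining amount to zero."""


class PoleWarning(UserWarning):
    """A rational expression was evaluated at (or next to) a pole."""
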