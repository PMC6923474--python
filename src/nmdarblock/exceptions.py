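"""Typed errors raised across the package."""


class NmdarBlockError(Exception):
    """Base class for all package errors."""


class ValidationError(NmdarBlockError, ValueError):
    """A domain object violates its invariants (negative rate, bad epoch, ...)."""


class UnitError(ValidationError):
    """A trace file declares units other than the package's fixed contract."""


class IntegrationError(NmdarBlockError, RuntimeError):
    """The master-equation integrator produced non-finite occupancies."""

    def __init__(self, message: str, t: float | None = None):
        super().__init__(message)
        self.t = t


class FitError(NmdarBlockError, RuntimeError):
    """A nonlinear fit failed to converge; carries the initial guesses."""

    def __init__(self, message: str, initial_guess=None):
        super().__init__(message)
        self.initial_guess = initial_guess


class InsufficientDataError(NmdarBlockError, ValueError):
    """Too few points/levels/groups for the requested estimate."""
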