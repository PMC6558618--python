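"""Exception types shared across the package."""


class EEGUQError(Exception):
    """Base class for package errors."""


class DomainError(EEGUQError):
    """A geometric or physical precondition is violated (e.g. a dipole
    placed outside the allowed source region)."""


class ConvergenceError(EEGUQError):
    """The spherical-harmonic series did not reach the requested relative
    tolerance within the maximum truncation degree."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual
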