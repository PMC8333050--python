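"""Exception hierarchy shared across the package."""


class CorrtomoError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(CorrtomoError):
    """Array shapes or supports incompatible with the requested operation."""


class ValidationError(CorrtomoError):
    """Invalid parameters or configuration (CLI exit code 2)."""


class DegenerateInputError(CorrtomoError):
    """Input is formally valid but carries no usable signal (all-zero, ...)."""


class NumericalFailureError(CorrtomoError):
    """Non-finite values appeared during iteration (CLI exit code 3)."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class MeasurementError(CorrtomoError):
    """A metric could not be evaluated on the given data (e.g. FWHM with no
    half-maximum crossing)."""
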