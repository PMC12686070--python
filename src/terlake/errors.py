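"""Exception hierarchy shared across the package."""


class TerlakeError(Exception):
    """Base class for package errors."""


class InvalidParameterError(TerlakeError, ValueError):
    """A parameter or input violates its documented domain."""


class NumericalFailureError(TerlakeError, RuntimeError):
    """An integrator or root finder failed irrecoverably."""


class InsufficientDataError(TerlakeError, ValueError):
    """Too few data points for the requested fit."""


class CalibrationError(TerlakeError, RuntimeError):
    """Light-regime calibration conditions violated."""
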