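"""Exception hierarchy.

``ValidationError`` covers malformed inputs (CLI exit code 1);
``RuntimeComputationError`` covers numerical failures (exit code 2).
"""


class StsnormError(Exception):
    """Base class for all package errors."""


class ValidationError(StsnormError, ValueError):
    """Input violates a documented precondition or invariant."""


class UnsupportedRateError(ValidationError):
    """Sample rate too low for the requested filter band."""


class NoSeatOffError(ValidationError):
    """Hip vertical force never drops below the seat-off threshold."""


class InvalidLoadingError(ValidationError):
    """Recording starts with the hip already unloaded."""


class TruncationError(ValidationError):
    """Requested trial window exceeds the recording bounds."""


class DegenerateInputError(ValidationError):
    """Input carries no usable signal (e.g. all-zero envelopes)."""


class RuntimeComputationError(StsnormError, RuntimeError):
    """Numerical failure during computation (non-finite output, no convergence)."""
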