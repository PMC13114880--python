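"""Exception hierarchy.

Two families matter downstream: :class:`ValidationError` (bad inputs,
CLI exit code 2) and :class:`NumericalError` (a computation that started
but failed, CLI exit code 3).
"""


class SpecbindError(Exception):
    """Base class for all package errors."""


class ValidationError(SpecbindError):
    """Input does not satisfy a precondition."""


class ParseError(ValidationError):
    """A file could not be parsed; message names the offending line."""


class SizeError(ValidationError):
    """Too few data points for the requested operation."""


class DataError(ValidationError):
    """Data values violate a physical precondition (e.g. F <= 0)."""


class DomainError(ValidationError):
    """Scalar argument outside its mathematical domain."""


class RangeError(ValidationError):
    """Requested window/region falls outside the data axis."""


class InputError(ValidationError):
    """Structurally invalid collection input (duplicates, unsorted...)."""


class MaskError(ValidationError):
    """Scatter masking removed the entire matrix."""


class FlatSignalError(ValidationError):
    """All intensities equal inside the search window; no peak exists."""


class SeedError(ValidationError):
    """Band seeding found no candidate centers."""


class AssignmentError(ValidationError):
    """A fitted band center lies outside the assignable region."""


class LimitError(ValidationError):
    """Quantity undefined at this limiting value (e.g. E = 0 or 1)."""


class NumericalError(SpecbindError):
    """A numerical procedure failed."""


class FitError(NumericalError):
    """Nonlinear fit did not converge; carries the best-so-far result."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class ConvergenceError(NumericalError):
    """Self-consistent iteration exceeded max_iter; carries a trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace
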