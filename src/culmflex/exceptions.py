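"""Exception hierarchy for culmflex."""


class CulmflexError(Exception):
    """Base class for all culmflex errors."""


class DomainError(CulmflexError, ValueError):
    """An input lies outside its admissible physical range."""


class GeometryError(CulmflexError, ValueError):
    """Degenerate or unphysical cross-section / beam geometry."""


class CalibrationError(CulmflexError, RuntimeError):
    """Geometry calibration could not match the homogenized target."""


class ConvergenceError(CulmflexError, RuntimeError):
    """Iterative solver failed to converge.

    Carries the iteration trace of the monitored quantity in
    :attr:`trace` so the failure can be inspected.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []


class RegimeError(CulmflexError, RuntimeError):
    """The load regime is outside the model's validity (fold-over)."""


class ComparisonError(CulmflexError, ZeroDivisionError):
    """A relative comparison against a vanishing reference quantity."""


class DegenerateInputError(CulmflexError, ValueError):
    """An all-zero or otherwise degenerate field was supplied."""
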