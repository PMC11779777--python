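"""Exception hierarchy shared across graphotrace modules."""


class GraphotraceError(Exception):
    """Base class for all package-specific errors."""


class InvalidProfileError(GraphotraceError):
    """A radial profile is geometrically invalid (non-positive radius)."""


class ConstructiveFailureError(GraphotraceError):
    """The equidistant ring could not be constructed within tolerance.

    Carries the diagnostic consecutive distances so the failure can be
    inspected.
    """

    def __init__(self, message: str, distances=None):
        super().__init__(message)
        self.distances = distances


class InvalidTraceError(GraphotraceError):
    """A pen trace violates its preconditions (e.g. no pen-down samples)."""


class UndefinedSmoothnessError(GraphotraceError):
    """Smoothness is undefined (e.g. all-zero speed profile)."""


class DegenerateInputError(GraphotraceError):
    """A statistical routine received degenerate input (e.g. zero variance)."""


class InfeasibleTargetError(GraphotraceError):
    """A calibration target is outside the attainable range."""


class SchemaError(GraphotraceError):
    """A file does not conform to the documented CSV/JSON dialect."""


class MissingCellError(GraphotraceError):
    """A balanced design is missing participant x condition cells."""
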