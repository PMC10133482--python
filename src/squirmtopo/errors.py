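"""Exception hierarchy for squirmtopo."""


class SquirmtopoError(Exception):
    """Base class for all package errors."""


class GeometryError(SquirmtopoError, ValueError):
    """Invalid discretisation parameter, off-surface point or domain violation."""


class ParameterError(SquirmtopoError, ValueError):
    """Invalid physical or numerical parameter (e.g. non-positive blob width)."""


class AssemblyError(SquirmtopoError, RuntimeError):
    """The linear system cannot be assembled (empty or duplicated collocation nodes)."""


class SolverError(SquirmtopoError, RuntimeError):
    """The assembled linear system could not be solved reliably."""


class IntegrationError(SquirmtopoError, RuntimeError):
    """Time integration failed; carries the last valid state."""

    def __init__(self, message, last_state=None, last_time=None):
        super().__init__(message)
        self.last_state = last_state
        self.last_time = last_time


class AnalysisError(SquirmtopoError, ValueError):
    """A trajectory post-processing request is ill-posed."""
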