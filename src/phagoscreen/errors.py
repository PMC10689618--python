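"""Exception types shared across the pipeline."""


class PhagoscreenError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(PhagoscreenError):
    """An input table is missing a required column or has the wrong layout."""


class TableParseError(PhagoscreenError):
    """A cell in an input table could not be parsed; carries the row number."""


class ValidationError(PhagoscreenError, ValueError):
    """An argument violates a documented precondition or invariant."""


class DegeneratePlateError(PhagoscreenError):
    """A plate has no usable wells for the requested summary (e.g. all green
    signal zero, or every data well flagged toxic)."""


class InsufficientDataError(PhagoscreenError):
    """Too few usable points for a fit."""


class StudyInfeasibleError(PhagoscreenError):
    """A cohort construction step produced an empty arm or no matches."""


class ConvergenceError(PhagoscreenError):
    """An iterative fitter failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace
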