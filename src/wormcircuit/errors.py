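"""Exception hierarchy.

Three broad classes map onto the CLI exit codes: configuration errors
(exit 2), file/format errors (exit 3) and compute errors (exit 4).
"""


class WormcircuitError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(WormcircuitError, ValueError):
    """A configuration value violates its documented constraints."""


class DomainError(WormcircuitError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class FormatError(WormcircuitError):
    """An input file does not match its expected layout."""


class SchemaError(FormatError):
    """A table is missing required columns or contains invalid records."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class ComputeError(WormcircuitError):
    """A numerical stage failed on otherwise well-formed inputs."""


class FitConvergenceError(ComputeError):
    """Curve fit failed to converge; carries the best parameters seen."""

    def __init__(self, message: str, best_params=None, diagnostics=None):
        super().__init__(message)
        self.best_params = best_params
        self.diagnostics = diagnostics or {}


class DegenerateFitError(ComputeError):
    """A fitted curve is unusable as a divisor (near zero somewhere)."""

    def __init__(self, message: str, time_index=None):
        super().__init__(message)
        self.time_index = time_index


class DegenerateBaselineError(ComputeError):
    """A pre-event baseline is non-positive, so a change ratio is undefined."""

    def __init__(self, message: str, event_index=None):
        super().__init__(message)
        self.event_index = event_index


class InsufficientBaselineError(ComputeError):
    """No event-free timepoints remain to fit a bleach baseline."""


class UndefinedCorrelationError(ComputeError):
    """Pearson correlation is undefined (zero variance in a trace)."""


class UndefinedTestError(ComputeError):
    """A statistical test is undefined for the given samples."""


class UnknownCellError(WormcircuitError, KeyError):
    """A requested cell label is absent from the lineage tree."""


class InsufficientSampleError(ComputeError):
    """A conditional estimate has no qualifying samples."""


class InsufficientTrackError(ComputeError):
    """A track is too short or too feature-poor for the requested metric."""


class DegenerateStepError(ComputeError):
    """A movement step has zero displacement, so its angle is undefined."""
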