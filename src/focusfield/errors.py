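"""Exception types shared across the pipeline stages."""


class FocusFieldError(Exception):
    """Base class for all package errors."""


class InvalidImageError(FocusFieldError, ValueError):
    """Input raster does not satisfy the image invariants."""


class InvalidParameterError(FocusFieldError, ValueError):
    """A configuration value is out of its legal range."""


class DegenerateStatsError(FocusFieldError, ValueError):
    """Frequency-band statistics are too degenerate for adaptive
    parameter estimation (e.g. a flat image with zero variance)."""


class ConvergenceError(FocusFieldError, RuntimeError):
    """Iteration cap reached before every neuron fired.

    Carries the partial state so callers can inspect what happened.
    """

    def __init__(self, message, state=None, edge=None):
        super().__init__(message)
        self.state = state
        self.edge = edge


class PipelineStageError(FocusFieldError, RuntimeError):
    """Wraps a stage failure with the name of the stage that raised it."""

    def __init__(self, stage, original):
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


class UndefinedMetricWarning(UserWarning):
    """A metric denominator was zero; the value is reported as NaN."""
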