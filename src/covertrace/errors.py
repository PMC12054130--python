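"""Exception and warning types shared across the package."""


class CoverTraceError(Exception):
    """Base class for all covertrace errors."""


class ParameterError(CoverTraceError, ValueError):
    """A simulation or analysis parameter violates its contract."""


class TraceFormatError(CoverTraceError, ValueError):
    """A trace file or in-memory trace violates the trace invariants."""


class FitDataError(CoverTraceError, ValueError):
    """Not enough usable samples to attempt a fit."""


class MetricUnavailableError(CoverTraceError, RuntimeError):
    """A metric was requested from a non-converged fit."""


class UndefinedCorrelationError(CoverTraceError, ValueError):
    """Correlation is undefined (e.g. a constant input vector)."""


class DegenerateTestError(CoverTraceError, ValueError):
    """A statistical test is degenerate (e.g. zero-variance differences)."""


class NyquistWarning(UserWarning):
    """A requested saccade is too fast to be represented at the sampling rate."""


class StabilizationWarning(UserWarning):
    """The 90% stabilization level was already exceeded at occlusion onset."""


class SmallDeviationWarning(UserWarning):
    """Fitted deviation amplitude is not clearly above the residual noise."""
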