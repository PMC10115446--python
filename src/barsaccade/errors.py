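"""Exception hierarchy used across the package."""


class BarSaccadeError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(BarSaccadeError, ValueError):
    """An argument violates a documented precondition."""


class InfeasibleConstraintError(BarSaccadeError, RuntimeError):
    """A stochastic generator could not satisfy its constraints within the retry budget."""


class DegenerateBaselineError(BarSaccadeError, ValueError):
    """The pre-stimulus fluorescence baseline is non-positive, so dF/F is undefined."""


class SchemaError(BarSaccadeError, ValueError):
    """A data file does not have the columns required for the requested trace kind."""


class InsufficientDataError(BarSaccadeError, ValueError):
    """Too few data points for the requested fit or comparison."""


class UndefinedArgmaxError(BarSaccadeError, ValueError):
    """A response row is identically zero, so its preferred stimulus is undefined."""


class UndefinedPIError(BarSaccadeError, ZeroDivisionError):
    """The stimulus displacement over the window is zero, so the performance index is undefined."""


class FitFailureError(BarSaccadeError, RuntimeError):
    """Nonlinear least squares failed to converge from every starting point."""
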