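"""Exception hierarchy shared across the package."""


class PopPKError(Exception):
    """Base class for all package errors."""


class ValidationError(PopPKError, ValueError):
    """Invalid user input or violated precondition."""


class FormatError(PopPKError, ValueError):
    """Malformed dataset file (missing column, bad dialect)."""


class UnsupportedOperationError(PopPKError):
    """Operation undefined for the given model (e.g. analytic results for a
    nonlinear-elimination model)."""


class NumericError(PopPKError, ArithmeticError):
    """Numerical failure (integrator blow-up, singular Hessian) with context."""


class ConvergenceError(PopPKError, RuntimeError):
    """Optimizer failed to converge; carries the best state found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best
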