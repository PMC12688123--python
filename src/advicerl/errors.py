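"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """A caller-supplied argument violates a documented precondition."""


class InvalidStateError(RuntimeError):
    """An operation was invoked in a state where it is undefined
    (e.g. querying social value on a masked trial)."""


class DataError(ValueError):
    """A data file or table violates the trial schema; message names the
    offending row/column where possible."""


class ConvergenceError(RuntimeError):
    """An MCMC fit failed its convergence diagnostics.  Carries the fit so
    the diagnostics can be inspected."""

    def __init__(self, message, fit=None):
        super().__init__(message)
        self.fit = fit
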