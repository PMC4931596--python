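"""Package exception hierarchy."""


class RodConfineError(Exception):
    """Base class for all rodconfine errors."""


class ConfigError(RodConfineError):
    """Invalid or inconsistent configuration input."""


class InitializationError(RodConfineError):
    """Packing initialization failed to reach the target diameter.

    Attributes
    ----------
    achieved_eta : float
        Packing fraction realized at the largest feasible diameter.
    """

    def __init__(self, message, achieved_eta=None):
        super().__init__(message)
        self.achieved_eta = achieved_eta


class ConvergenceError(RodConfineError):
    """Iterative minimization failed to converge.

    Carries the free-energy trace recorded up to the failure.
    """

    def __init__(self, message, energy_trace=None):
        super().__init__(message)
        self.energy_trace = energy_trace


class AnalysisError(RodConfineError):
    """Field analysis could not be carried out on the given input."""
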