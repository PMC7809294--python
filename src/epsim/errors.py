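"""Exception hierarchy for the simulator."""


class EpsimError(Exception):
    """Base class for all simulator errors."""


class ConfigurationError(EpsimError, ValueError):
    """Invalid configuration values (domain, protocol, schema)."""


class GeometryError(EpsimError, ValueError):
    """Electrode geometry problems: overlap, outside the domain, no nodes claimed."""


class SolverError(EpsimError, RuntimeError):
    """Iterative solver failed to converge.

    Carries the final relative residual and the iteration count.
    """

    def __init__(self, message: str, residual: float | None = None,
                 iterations: int | None = None):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


class StateError(EpsimError, ValueError):
    """Non-physical field state (e.g. conductivity <= 0)."""
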