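"""Exception hierarchy.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
NumericalError (SimulationError, FitError) -> 4.
"""


class FloodmetError(Exception):
    """Base class for all package errors."""


class ConfigError(FloodmetError):
    """Invalid model configuration or pipeline configuration."""


class DataError(FloodmetError):
    """Invalid or incomplete observed data (profiles, protein tables)."""


class ParameterError(FloodmetError, ValueError):
    """Invalid numeric argument to an operation."""


class LookupError_(FloodmetError, KeyError):
    """Unknown reaction or metabolite identifier."""


class NumericalError(FloodmetError):
    """Numerical failure (integration or optimisation)."""


class SimulationError(NumericalError):
    """ODE integration failed; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


class FitError(NumericalError):
    """Vmax optimisation failed; carries the best result seen so far."""

    def __init__(self, message: str, best_result=None):
        super().__init__(message)
        self.best_result = best_result
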