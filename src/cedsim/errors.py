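"""Exception hierarchy for cedsim."""


class CedsimError(Exception):
    """Base class for all cedsim errors."""


class ParameterError(CedsimError, ValueError):
    """A physical parameter is outside its admissible range."""


class DomainTooSmallError(CedsimError):
    """The concentration front reached the outer edge of the solver domain."""


class SolverError(CedsimError):
    """Numerical failure inside the PDE solver."""


class FitError(CedsimError):
    """Nonlinear fit failed to converge.

    Carries the last iterate so callers can inspect where the optimizer
    stalled.
    """

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class UnderDeterminedError(CedsimError, ValueError):
    """Fewer data points than free parameters."""


class InfeasibleGeometryError(CedsimError, ValueError):
    """Requested cylinder dimensions cannot enclose the requested volume."""


class NoCrossingError(CedsimError):
    """A concentration profile never crosses the requested threshold.

    Most call sites should use the ``None`` return of
    :func:`cedsim.metrics.crossing_radius` instead of catching this.
    """


class ConfigError(CedsimError, ValueError):
    """Invalid or unknown keys in a run-configuration file."""
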