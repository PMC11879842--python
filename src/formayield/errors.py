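"""Exception hierarchy for formayield."""


class FormaYieldError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FormaYieldError):
    """A file could not be parsed (message names the offending line)."""


class ValidationError(FormaYieldError):
    """A model or table violates a structural invariant."""


class ModelEditError(FormaYieldError):
    """A pathway-variant or biomass edit could not be applied."""


class YieldError(FormaYieldError):
    """Yield prediction failed.

    When the requested growth rate is infeasible, ``max_feasible_mu`` holds
    the largest feasible growth rate found by bisection.
    """

    def __init__(self, message: str, max_feasible_mu: float | None = None):
        super().__init__(message)
        self.max_feasible_mu = max_feasible_mu


class ConstraintError(FormaYieldError):
    """An MDF concentration-constraint set is inconsistent."""


class RouteError(FormaYieldError):
    """A route's internal intermediates cannot be eliminated."""


class StatsError(FormaYieldError):
    """Insufficient or malformed data for a statistical comparison."""
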