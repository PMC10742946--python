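"""Exception hierarchy for recotherm."""


class RecothermError(Exception):
    """Base class for all recotherm errors."""


class ValidationError(RecothermError, ValueError):
    """An input object violates its invariants beyond tolerance."""


class UndefinedPosteriorError(RecothermError, ZeroDivisionError):
    """Posterior requested at a received message with zero marginal probability."""


class UndefinedRatioError(RecothermError, ZeroDivisionError):
    """A log-ratio of two probabilities that are both zero."""


class InfeasibleStrengthsError(RecothermError, ValueError):
    """A nonequilibrium strength vector d outside the feasible region for its m."""


class ConvergenceError(RecothermError, RuntimeError):
    """An iterative limit (e.g. the coarse-grained kernel) failed to converge."""
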