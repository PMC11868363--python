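"""Exception hierarchy for usirhf."""


class UsirhfError(Exception):
    """Base class for all usirhf-specific errors."""


class InvalidParameterError(UsirhfError, ValueError):
    """A parameter is outside its admissible range."""


class InfeasiblePatternError(UsirhfError, RuntimeError):
    """The requested sampling fraction cannot be reached on this grid."""


class DimensionError(UsirhfError, ValueError):
    """Array shapes are inconsistent."""


class SolverDivergenceError(UsirhfError, RuntimeError):
    """The iterative solver's objective increased persistently.

    Carries the objective trace in ``trace``.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []


class IllConditionedError(UsirhfError, RuntimeError):
    """A parallel-imaging unfolding system is unresolvable."""


class NoEdgeError(UsirhfError, ValueError):
    """No usable high-contrast edge found in the requested region."""


class InsufficientDataError(UsirhfError, ValueError):
    """Not enough samples/cycles to compute the requested statistic."""


class UndefinedRatioError(UsirhfError, ValueError):
    """A ratio-type metric is undefined (zero denominator)."""


class DegenerateMarginalsError(UsirhfError, ValueError):
    """Agreement statistic undefined: both raters constant in one category."""


class ConfigError(UsirhfError, ValueError):
    """An experiment configuration file is malformed or invalid."""
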