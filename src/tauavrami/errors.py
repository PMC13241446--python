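"""Typed exceptions shared across the package.

Every failure mode a caller might want to branch on gets its own class;
all inherit from :class:`TauAvramiError` so ``except TauAvramiError``
catches anything raised deliberately by this package.
"""


class TauAvramiError(Exception):
    """Base class for all errors raised by tauavrami."""


class InvalidArgumentError(TauAvramiError, ValueError):
    """An input violates a documented precondition (non-finite, out of range...)."""


class NumericalError(TauAvramiError, ArithmeticError):
    """A numerical routine failed to converge to the requested tolerance."""


class KineticsOverflowError(NumericalError, OverflowError):
    """An exponential in the kinetics would overflow double precision.

    Carries the offending exponent so callers can rescale time units.
    """

    def __init__(self, exponent: float, context: str = ""):
        self.exponent = float(exponent)
        msg = f"exponent {exponent:.6g} exceeds the overflow guard (700)"
        if context:
            msg += f" in {context}"
        super().__init__(msg)


class InfeasibleMeanError(TauAvramiError):
    """The mean-enforcement equation has no solution.

    Raised when the target spatial mean X(t) exceeds the fraction of nodes
    with a positive weighted extended variable: the node-mean of
    1 - exp(-S*b_i) cannot reach X even as S -> infinity.
    """

    def __init__(self, target: float, positive_fraction: float, time: float | None = None):
        self.target = float(target)
        self.positive_fraction = float(positive_fraction)
        self.time = time
        at = f" at t={time:g} days" if time is not None else ""
        super().__init__(
            f"mean tau target X={target:.6g} is unreachable{at}: only a fraction "
            f"{positive_fraction:.6g} of nodes carries positive weight"
        )


class FormatError(TauAvramiError, ValueError):
    """A file being read does not conform to the expected format."""
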