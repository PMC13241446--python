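"""Project the homogeneous kinetics onto a nodal mechanical-strain field.

A finite-element impact simulation yields a scalar per mesh node (e.g.
logarithmic maximum principal strain).  The field is min-max normalized
to w_i in [0, 1], raised to the fourth power to sharpen spatial contrast
(w^4 is a modelling assumption; the exponent is configurable), and used
to weight the extended volume locally:

    Y_i(t) = A^p w_i^p Y_e(t)            (p = 4, A = impact amplitude)
    tau_i(t) = 1 - exp(-S(t) Y_i(t))

The time-dependent correction factor S(t) is the unique root of

    (1/N) sum_i (1 - exp(-S A^p w_i^p Y_e)) = X(t) = alpha (1 - exp(-Y_e))

so the unweighted node-mean of the local tau map reproduces the
calibrated homogeneous curve exactly while the mechanics decide *where*
tau accumulates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import InfeasibleMeanError, InvalidArgumentError, NumericalError
from .kinetics import (
    KineticParameters,
    SaturationBound,
    TimeGrid,
    extended_volume,
)

__all__ = [
    "MechanicalField",
    "NormalizedField",
    "AmplitudeFactor",
    "TauFieldSeries",
    "normalize_field",
    "local_extended",
    "solve_correction",
    "tau_map",
    "DEFAULT_OUTPUT_TIMES",
]

#: Output time grid of the spatiotemporal maps (days).
DEFAULT_OUTPUT_TIMES = (1.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0, 350.0)

#: Largest double strictly below 1: local tau is < 1 by construction.
_BELOW_ONE = float(np.nextafter(1.0, 0.0))


@dataclass(frozen=True)
class MechanicalField:
    """Raw nodal scalar field w0 (arbitrary units) over mesh nodes."""

    node_ids: np.ndarray
    w0: np.ndarray
    coordinates: np.ndarray | None = None

    def __post_init__(self):
        ids = np.asarray(self.node_ids)
        w0 = np.asarray(self.w0, dtype=float)
        object.__setattr__(self, "node_ids", ids)
        object.__setattr__(self, "w0", w0)
        if ids.ndim != 1 or w0.ndim != 1 or ids.size != w0.size or ids.size == 0:
            raise InvalidArgumentError("node_ids and w0 must be equal-length 1-D, >= 1 node")
        if np.unique(ids).size != ids.size:
            raise InvalidArgumentError("node_ids must be unique")
        if not np.all(np.isfinite(w0)):
            bad = ids[~np.isfinite(w0)]
            raise InvalidArgumentError(f"non-finite w0 at nodes {bad[:10].tolist()}")
        if self.coordinates is not None:
            xyz = np.asarray(self.coordinates, dtype=float)
            object.__setattr__(self, "coordinates", xyz)
            if xyz.shape != (ids.size, 3) or not np.all(np.isfinite(xyz)):
                raise InvalidArgumentError("coordinates must be a finite (N, 3) array")

    @property
    def n_nodes(self) -> int:
        return int(self.node_ids.size)


@dataclass(frozen=True)
class NormalizedField:
    """Min-max normalized field w in [0, 1] plus the raw min/max provenance."""

    node_ids: np.ndarray
    w: np.ndarray
    w0_min: float
    w0_max: float
    coordinates: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return int(self.node_ids.size)


@dataclass(frozen=True)
class AmplitudeFactor:
    """Global impact-amplitude factor A = (Q/Q_ref)(N/N_ref).

    Encodes impact magnitude Q and impact count N relative to reference
    values.  The default A = 1 leaves the normalized field in charge of
    all spatial variation.
    """

    Q: float = 1.0
    Q_ref: float = 1.0
    n_impacts: float = 1.0
    n_ref: float = 1.0

    def __post_init__(self):
        for name in ("Q", "Q_ref", "n_impacts", "n_ref"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidArgumentError(f"{name} must be positive and finite, got {v}")

    @property
    def A(self) -> float:
        return (self.Q / self.Q_ref) * (self.n_impacts / self.n_ref)


@dataclass(frozen=True)
class TauFieldSeries:
    """Per-node tau over a time grid, with the correction factors S(t)."""

    node_ids: np.ndarray
    times: np.ndarray
    tau: np.ndarray  # shape (n_nodes, n_times)
    s_factors: np.ndarray  # shape (n_times,)
    exponent: float = 4.0

    def spatial_mean(self) -> np.ndarray:
        """Unweighted node-mean of tau at each time."""
        return self.tau.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (node_id, time_days, tau) table."""
        n, t = self.tau.shape
        return pd.DataFrame(
            {
                "node_id": np.repeat(self.node_ids, t),
                "time_days": np.tile(self.times, n),
                "tau": self.tau.ravel(),
            }
        )

    def s_table(self) -> pd.DataFrame:
        return pd.DataFrame({"time_days": self.times, "s_factor": self.s_factors})


def normalize_field(field: MechanicalField) -> NormalizedField:
    """Min-max normalize the raw field to [0, 1].

    A constant raw field is the 0/0 corner of the normalization; by
    convention it maps to w = 1 everywhere, so the heterogeneous model
    degrades gracefully to the homogeneous curve.
    """
    lo = float(np.min(field.w0))
    hi = float(np.max(field.w0))
    if hi == lo:
        w = np.ones_like(field.w0)
    else:
        w = (field.w0 - lo) / (hi - lo)
    return NormalizedField(
        node_ids=field.node_ids,
        w=w,
        w0_min=lo,
        w0_max=hi,
        coordinates=field.coordinates,
    )


def local_extended(
    w: NormalizedField,
    amp: AmplitudeFactor = AmplitudeFactor(),
    ye: float = 0.0,
    exponent: float = 4.0,
) -> np.ndarray:
    """Per-node weighted extended variable Y_i = A^p w_i^p Y_e."""
    if not (math.isfinite(ye) and ye >= 0):
        raise InvalidArgumentError(f"ye must be finite and >= 0, got {ye}")
    return (amp.A**exponent) * (w.w**exponent) * ye


def _weights(w: NormalizedField, amp: AmplitudeFactor, exponent: float) -> np.ndarray:
    return (amp.A**exponent) * (w.w**exponent)


def _solve_correction_on(b: np.ndarray, target: float, tol: float) -> float:
    """Root of mean(1 - exp(-S b)) = target in S >= 0 (b fixed, some b > 0)."""

    def g(s: float) -> float:
        return float(np.mean(-np.expm1(-s * b))) - target

    hi = 1.0
    for _ in range(200):
        if g(hi) > 0.0:
            break
        hi *= 2.0
    else:  # pragma: no cover - guarded by the feasibility check
        raise NumericalError("could not bracket the correction factor S")
    s = optimize.brentq(g, 0.0, hi, xtol=1e-30, rtol=8.9e-16, maxiter=200)
    # brentq terminates on the bracket width; polish by bisection until the
    # residual on the *mean* is inside tol.
    if abs(g(s)) > tol:
        lo_, hi_ = 0.0, hi
        for _ in range(200):
            mid = 0.5 * (lo_ + hi_)
            if g(mid) < 0:
                lo_ = mid
            else:
                hi_ = mid
            if abs(g(mid)) <= tol:
                s = mid
                break
    return float(s)


def solve_correction(
    w: NormalizedField,
    amp: AmplitudeFactor = AmplitudeFactor(),
    ye: float = 0.0,
    bound: SaturationBound = SaturationBound(),
    tol: float = 1e-10,
    exponent: float = 4.0,
) -> float:
    """Solve for the mean-enforcing correction factor S at one extended volume.

    The node-mean of 1 - exp(-S b_i) (b_i = A^p w_i^p Y_e) is strictly
    increasing in S and saturates at the fraction of nodes with b_i > 0,
    so the root is unique when the target X = alpha (1 - exp(-Y_e)) is
    reachable; otherwise InfeasibleMeanError is raised.  At Y_e = 0 the
    equation is vacuous (any S solves it) and S = 1 is returned by
    convention.
    """
    if not (math.isfinite(ye) and ye >= 0):
        raise InvalidArgumentError(f"ye must be finite and >= 0, got {ye}")
    if ye == 0.0:
        return 1.0
    target = bound.alpha * -math.expm1(-ye)
    b = _weights(w, amp, exponent) * ye
    positive_fraction = float(np.mean(b > 0))
    if target >= positive_fraction:
        raise InfeasibleMeanError(target, positive_fraction)
    return _solve_correction_on(b, target, tol)


def tau_map(
    w: NormalizedField,
    amp: AmplitudeFactor = AmplitudeFactor(),
    params: KineticParameters = None,
    bound: SaturationBound = SaturationBound(),
    grid: TimeGrid | Sequence[float] = DEFAULT_OUTPUT_TIMES,
    exponent: float = 4.0,
    tol: float = 1e-10,
) -> TauFieldSeries:
    """Spatiotemporal tau map tau_i(t) = 1 - exp(-S(t) A^p w_i^p Y_e(t)).

    For each grid time the homogeneous extended volume is evaluated, the
    correction factor solved, and the local law applied.  The node-mean
    equals X(t) to within ``tol`` at every time, and tau inherits the
    ordering of w across nodes.
    """
    if params is None:
        raise InvalidArgumentError("params is required")
    if not isinstance(grid, TimeGrid):
        grid = TimeGrid(grid)
    times = grid.as_array()
    weights = _weights(w, amp, exponent)
    positive_fraction = float(np.mean(weights > 0))
    tau = np.zeros((w.n_nodes, times.size))
    s_factors = np.ones(times.size)
    for j, t in enumerate(times):
        ye = extended_volume(t, params)
        if ye == 0.0:
            s_factors[j] = 1.0
            continue
        target = bound.alpha * -math.expm1(-ye)
        if target >= positive_fraction:
            raise InfeasibleMeanError(target, positive_fraction, time=t)
        s = _solve_correction_on(weights * ye, target, tol)
        s_factors[j] = s
        # 1 - exp(-S b) < 1 mathematically; keep it strictly below 1 where
        # exp underflows (the clip is < 1 ulp of error)
        tau[:, j] = np.minimum(-np.expm1(-s * weights * ye), _BELOW_ONE)
    return TauFieldSeries(
        node_ids=w.node_ids,
        times=times,
        tau=tau,
        s_factors=s_factors,
        exponent=exponent,
    )
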