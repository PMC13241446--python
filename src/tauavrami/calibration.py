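"""Fit the Avrami kinetic parameters to a tau-burden time series.

The fitting target is a handful of (time, tau) pairs, e.g. the four-point
murine AT% series at days 1/7/60/180.  The objective is the mean squared
error between the saturated homogeneous curve X(t) and the observations,
minimised by the two-step procedure the field standardly uses for rough
multi-modal landscapes: a broad seeded random exploration of parameter
space followed by Nelder-Mead refinement of the best candidates.

Identifiability.  v0 and J0 enter Y_e only through the product
C = J0 * v0**3 (together with kv, kJ in the exponents), so only
(C, kv, kJ) can be determined from a tau time series.  The search and the
simplex therefore operate on the reduced coordinates (log C, kv, kJ);
the four-parameter representation is recovered by pinning v0 to a
configurable reference velocity and setting J0 = C / v_ref**3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import InvalidArgumentError, NumericalError, TauAvramiError
from .kinetics import (
    KineticParameters,
    SaturationBound,
    TimeGrid,
    trajectory,
)

__all__ = [
    "ObservationSeries",
    "SearchConfig",
    "Candidate",
    "RefineResult",
    "CalibrationResult",
    "mse_objective",
    "global_search",
    "refine",
    "calibrate",
    "goodness_of_fit",
]

#: Numeric penalty returned by the objective when the model overflows,
#: so derivative-free optimizers can step around the bad region.
OVERFLOW_PENALTY = 1e12


@dataclass(frozen=True)
class ObservationSeries:
    """(time, tau) calibration pairs; days and AT%-units."""

    times: tuple[float, ...]
    tau: tuple[float, ...]

    def __init__(self, times: Sequence[float], tau: Sequence[float], alpha: float = 0.35):
        t = np.asarray(list(times), dtype=float)
        y = np.asarray(list(tau), dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise InvalidArgumentError("times and tau must be 1-D and of equal length")
        if t.size < 2:
            raise InvalidArgumentError("at least 2 observations are required")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise InvalidArgumentError("observations must be finite")
        if np.any(t <= 0) or not np.all(np.diff(t) > 0):
            raise InvalidArgumentError("times must be positive and strictly increasing")
        if np.any(y < 0) or np.any(y >= alpha):
            raise InvalidArgumentError(
                f"tau values must lie in [0, alpha={alpha}); got {y}"
            )
        object.__setattr__(self, "times", tuple(float(v) for v in t))
        object.__setattr__(self, "tau", tuple(float(v) for v in y))

    def grid(self) -> TimeGrid:
        return TimeGrid(self.times)

    def tau_array(self) -> np.ndarray:
        return np.asarray(self.tau, dtype=float)

    @classmethod
    def from_csv(cls, path) -> "ObservationSeries":
        from .io import read_observations_csv

        return read_observations_csv(path)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_days": self.times, "tau_at_percent": self.tau}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class SearchConfig:
    """Settings of the two-step calibration.

    seed is mandatory: every random draw flows from it.  Bounds are in the
    reduced space — c_bounds are log-uniform sampling limits on
    C = J0 v0^3, k bounds are uniform limits on the modulation
    coefficients in day^-1.  v_ref is the reference growth velocity used
    to expand the reduced optimum back to four parameters.
    """

    seed: int
    n_samples: int = 50_000
    c_bounds: tuple[float, float] = (1e-14, 1e-2)
    kv_bounds: tuple[float, float] = (-0.1, 0.1)
    kj_bounds: tuple[float, float] = (-0.1, 0.1)
    n_restarts: int = 5
    simplex_tol: float = 1e-12
    max_iter: int = 10_000
    v_ref: float = 0.0472197

    def __post_init__(self):
        if self.n_samples < 1:
            raise InvalidArgumentError("n_samples must be >= 1")
        if self.n_restarts < 1:
            raise InvalidArgumentError("n_restarts must be >= 1")
        for name in ("c_bounds", "kv_bounds", "kj_bounds"):
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise InvalidArgumentError(f"{name} must be finite and well-ordered")
        if self.c_bounds[0] <= 0:
            raise InvalidArgumentError("c_bounds must be positive (log-uniform sampling)")
        if self.simplex_tol <= 0 or self.max_iter < 1 or self.v_ref <= 0:
            raise InvalidArgumentError("simplex_tol, max_iter and v_ref must be positive")


class Candidate(NamedTuple):
    params: KineticParameters
    objective: float


@dataclass(frozen=True)
class RefineResult:
    params: KineticParameters
    objective: float
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class CalibrationResult:
    """Best-fit parameters plus the fit diagnostics."""

    params: KineticParameters
    predicted: np.ndarray
    residuals: np.ndarray
    rmse: float
    r2: float
    objective_trace: tuple[float, ...]
    converged: bool
    config: SearchConfig
    observations: ObservationSeries

    def prediction_table(self) -> pd.DataFrame:
        obs = self.observations.tau_array()
        return pd.DataFrame(
            {
                "time_days": self.observations.times,
                "tau_observed": obs,
                "tau_predicted": self.predicted,
                "abs_error": np.abs(self.residuals),
            }
        )

    def to_report(self) -> dict:
        p = self.params
        return {
            "parameters": {"v0": p.v0, "J0": p.J0, "kv": p.kv, "kJ": p.kJ},
            "reduced": {"C": p.J0 * p.v0**3, "kv": p.kv, "kJ": p.kJ},
            "rmse": self.rmse,
            "r2": self.r2,
            "converged": self.converged,
            "objective_trace": list(self.objective_trace),
            "predictions": self.prediction_table().to_dict(orient="records"),
            "config": {
                "seed": self.config.seed,
                "n_samples": self.config.n_samples,
                "c_bounds": list(self.config.c_bounds),
                "kv_bounds": list(self.config.kv_bounds),
                "kj_bounds": list(self.config.kj_bounds),
                "n_restarts": self.config.n_restarts,
                "simplex_tol": self.config.simplex_tol,
                "max_iter": self.config.max_iter,
                "v_ref": self.config.v_ref,
            },
        }


# ---------------------------------------------------------------------------


def _expand(log_c: float, kv: float, kj: float, v_ref: float) -> KineticParameters:
    c = math.exp(log_c)
    return KineticParameters(v0=v_ref, J0=c / v_ref**3, kv=kv, kJ=kj)


def mse_objective(
    params: KineticParameters,
    obs: ObservationSeries,
    bound: SaturationBound = SaturationBound(),
) -> float:
    """Mean squared error of X(t) against the observations.

    Numeric failures inside the model (overflow, quadrature breakdown)
    are encoded as a large finite penalty so optimizers keep going.
    """
    try:
        traj = trajectory(obs.grid(), params, bound)
    except (NumericalError, OverflowError):
        return OVERFLOW_PENALTY
    res = traj.x - obs.tau_array()
    return float(np.mean(res**2))


def global_search(
    obs: ObservationSeries,
    config: SearchConfig,
    bound: SaturationBound = SaturationBound(),
) -> list[Candidate]:
    """Broad seeded random exploration of the reduced parameter space.

    Draws n_samples points (log-uniform C, uniform kv, kJ), scores each by
    mse_objective, and returns candidates sorted by objective ascending.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    log_c = rng.uniform(
        math.log(config.c_bounds[0]), math.log(config.c_bounds[1]), config.n_samples
    )
    kv = rng.uniform(*config.kv_bounds, config.n_samples)
    kj = rng.uniform(*config.kj_bounds, config.n_samples)
    cands = []
    for i in range(config.n_samples):
        p = _expand(log_c[i], kv[i], kj[i], config.v_ref)
        cands.append(Candidate(p, mse_objective(p, obs, bound)))
    cands.sort(key=lambda c: (c.objective, c.params.kv, c.params.kJ, c.params.J0))
    return cands


def refine(
    start: KineticParameters,
    obs: ObservationSeries,
    config: SearchConfig,
    bound: SaturationBound = SaturationBound(),
) -> RefineResult:
    """Nelder-Mead refinement in (log C, kv, kJ) from a start point.

    The simplex is kept inside the configured parameter box by a
    quadratic penalty (the objective is evaluated at the clipped point),
    so refined modulation coefficients stay in ranges where the kinetics
    remain evaluable over year-scale horizons.  The returned objective
    never exceeds the start's: if the simplex ends worse (it cannot, but
    the contract is enforced anyway) the start is returned.
    ``converged`` is False when the iteration cap was hit.
    """
    if start.J0 <= 0:
        raise InvalidArgumentError("refine requires J0 > 0 (log C coordinate)")
    x0 = np.array([math.log(start.J0 * start.v0**3), start.kv, start.kJ])
    lo = np.array([math.log(config.c_bounds[0]), config.kv_bounds[0], config.kj_bounds[0]])
    hi = np.array([math.log(config.c_bounds[1]), config.kv_bounds[1], config.kj_bounds[1]])

    def f(x):
        xc = np.clip(x, lo, hi)
        penalty = 1e3 * float(np.sum((x - xc) ** 2))
        try:
            p = _expand(xc[0], xc[1], xc[2], config.v_ref)
        except (OverflowError, InvalidArgumentError):
            return OVERFLOW_PENALTY
        return mse_objective(p, obs, bound) + penalty

    res = optimize.minimize(
        f,
        x0,
        method="Nelder-Mead",
        options={
            "fatol": config.simplex_tol,
            "xatol": 1e-10,
            "maxiter": config.max_iter,
            "maxfev": 4 * config.max_iter,
        },
    )
    f0 = f(x0)
    if res.fun <= f0:
        xc = np.clip(res.x, lo, hi)
        params = _expand(xc[0], xc[1], xc[2], config.v_ref)
        obj = mse_objective(params, obs, bound)
    else:  # pragma: no cover - Nelder-Mead keeps the best vertex
        params, obj = start, f0
    return RefineResult(
        params=params, objective=obj, converged=bool(res.success), n_iter=int(res.nit)
    )


def calibrate(
    obs: ObservationSeries,
    config: SearchConfig,
    bound: SaturationBound = SaturationBound(),
) -> CalibrationResult:
    """Two-step calibration: global random search, then simplex refinement.

    The top ``n_restarts`` search candidates are refined independently and
    the best refined point wins.  The objective trace records the best
    objective after the search stage and after each refinement.
    """
    cands = global_search(obs, config, bound)
    trace = [cands[0].objective]
    best: RefineResult | None = None
    for cand in cands[: config.n_restarts]:
        if cand.params.J0 <= 0:
            continue
        r = refine(cand.params, obs, config, bound)
        trace.append(r.objective)
        if best is None or r.objective < best.objective:
            best = r
    if best is None:
        raise TauAvramiError("no refinable candidate found (all J0 <= 0)")
    traj = trajectory(obs.grid(), best.params, bound)
    observed = obs.tau_array()
    residuals = traj.x - observed
    rmse, r2 = goodness_of_fit(observed, traj.x)
    return CalibrationResult(
        params=best.params,
        predicted=traj.x,
        residuals=residuals,
        rmse=rmse,
        r2=r2,
        objective_trace=tuple(trace),
        converged=best.converged,
        config=config,
        observations=obs,
    )


def goodness_of_fit(observed, predicted) -> tuple[float, float]:
    """RMSE and coefficient of determination R^2 (about the observed mean)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 2:
        raise InvalidArgumentError("observed and predicted must be 1-D, equal length >= 2")
    res = pred - obs
    rmse = float(np.sqrt(np.mean(res**2)))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise InvalidArgumentError("R^2 undefined: observed values have zero variance")
    r2 = 1.0 - float(np.sum(res**2)) / ss_tot
    return rmse, r2
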