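"""Least-squares estimation of systemic parameters (oral data) and nasal
deposition fractions (intranasal data).

The fitting strategy mirrors the three-step scheme used to parameterise
the model: systemic disposition (tlag, ka, Vc, CL) is estimated from mean
oral profiles per population; with systemic parameters frozen, the nasal
and pharyngeal deposition fractions (F1, F2) are estimated from the mean
intranasal profile, with the lower-airway fractions fixed at 0.

Weighted least squares on the mean profile; default weighting 1/yhat^2
(proportional error).  Zero-valued observations are below-LLOQ censorings
and carry no information under least squares — they are excluded.  The
optimiser is a bounded-transform Nelder–Mead simplex with seeded jittered
restarts (few parameters, objective non-smooth in the lag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .model import (DepositionFractions, DoseEvent, Regimen, SystemicParams,
                    simulate)
from .physiology import PhysiologyConstants

Weighting = Literal["uniform", "1/y", "1/y^2"]

_PRED_FLOOR = 1e-10  # ng/mL; guards proportional weights against pred == 0


class FittingError(ValueError):
    pass


@dataclass(frozen=True)
class ObservedSeries:
    """A mean concentration–time profile with assay metadata.

    ``conc`` values below ``lloq`` are stored as 0 (the source studies
    record sub-LLOQ means as zero); ``dose`` is the administered amount in
    ng and ``route`` one of ``oral``/``intranasal``.
    """

    label: str
    times: tuple[float, ...]
    conc: tuple[float, ...]
    lloq: float
    dose: float
    route: str
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        conc = tuple(float(c) for c in self.conc)
        if len(times) != len(conc):
            raise FittingError("times and conc must have equal length")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise FittingError("times must be strictly increasing")
        if any(c < 0 for c in conc):
            raise FittingError("concentrations must be >= 0")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "meta", dict(self.meta))


@dataclass
class FitResult:
    estimates: dict[str, float]
    objective: float
    converged: bool
    n_obs: int
    weighting: Weighting
    trace: list[float] = field(default_factory=list)
    message: str = ""


def objective(obs: ObservedSeries, pred: Sequence[float],
              weighting: Weighting = "1/y^2") -> float:
    """Weighted sum of squared residuals over quantifiable observations.

    Weights are prediction-based: 1, 1/yhat or 1/yhat^2.  The 1/yhat^2
    scheme is scale-invariant (common c cancels).
    """
    pred = np.asarray(pred, dtype=float)
    c = np.asarray(obs.conc, dtype=float)
    if len(pred) != len(c):
        raise FittingError("pred must align with obs.times")
    keep = c > 0
    if not keep.any():
        raise FittingError("all observations are below LLOQ")
    r = c[keep] - pred[keep]
    yhat = np.maximum(pred[keep], _PRED_FLOOR)
    if weighting == "uniform":
        w = np.ones_like(yhat)
    elif weighting == "1/y":
        w = 1.0 / yhat
    elif weighting == "1/y^2":
        w = 1.0 / yhat ** 2
    else:
        raise FittingError(f"unknown weighting {weighting!r}")
    return float(np.sum(w * r * r))


def _predict_plasma(obs: ObservedSeries, phys: PhysiologyConstants,
                    sys: SystemicParams, frac: DepositionFractions) -> np.ndarray:
    grid = np.asarray(obs.times, dtype=float)
    if grid[0] > 0:
        grid = np.concatenate([[0.0], grid])
        skip = 1
    else:
        skip = 0
    regimen = Regimen(events=(DoseEvent(0.0, obs.route, obs.dose),))
    sim = simulate(phys, sys, frac, regimen, grid)
    return sim.C_plasma[skip:]


def _run_simplex(fun, x0: np.ndarray, n_restarts: int, seed: int,
                 jitter: float = 0.3, maxiter: int = 600,
                 spread: float = 0.5) -> tuple[np.ndarray, float, bool, list[float]]:
    """Nelder–Mead with seeded jittered restarts.

    A wide initial simplex (``spread`` per transformed coordinate) lets the
    reflection step escape the flat region created by a lag time sitting
    above an early sampling point (all predictions there are zero, so the
    objective is locally constant in the lag).
    """
    rng = np.random.default_rng(seed)
    starts = [np.asarray(x0, dtype=float)]
    starts += [x0 + jitter * rng.standard_normal(len(x0))
               for _ in range(max(0, n_restarts - 1))]
    best_x, best_f, ok = None, math.inf, False
    trace: list[float] = []

    def wrapped(x):
        f = fun(x)
        if not trace or f < trace[-1]:
            trace.append(f)
        return f

    n = len(x0)
    for x_start in starts:
        simplex = np.vstack([x_start, x_start + spread * np.eye(n)])
        res = minimize(wrapped, x_start, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-8,
                                "fatol": 1e-12, "initial_simplex": simplex})
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
            ok = bool(res.success)
    assert best_x is not None
    return best_x, best_f, ok, trace


def fit_systemic(obs: ObservedSeries, phys: PhysiologyConstants,
                 init: SystemicParams,
                 tlag_bounds: tuple[float, float] = (0.0, 2.0),
                 weighting: Weighting = "1/y^2", n_restarts: int = 5,
                 seed: int = 0, maxiter: int = 600) -> FitResult:
    """Estimate (tlag, ka, Vc, CL) from a mean oral profile.

    tlag is optimised through a logistic transform onto ``tlag_bounds``;
    ka, Vc, CL through log transforms (positivity).  The upper lag bound is
    additionally capped at the first quantifiable sampling time — a longer
    lag predicts zero there, which is inconsistent with the data and leaves
    the objective flat in the lag.  Peripheral exchange stays fixed at zero.
    """
    if obs.route != "oral":
        raise FittingError("fit_systemic requires an oral series")
    frac = DepositionFractions(F1=0.0, F2=0.0)
    lo, hi = tlag_bounds
    first_positive = next((t for t, c in zip(obs.times, obs.conc) if c > 0), hi)
    hi = min(hi, first_positive)
    if hi <= lo:
        raise FittingError("no quantifiable observation after the lag window")
    span = hi - lo

    def pack(p: SystemicParams) -> np.ndarray:
        # keep the start away from the saturated tails of the logit
        frac_lag = min(max((p.tlag - lo) / span, 0.05), 0.95)
        return np.array([math.log(frac_lag / (1.0 - frac_lag)),
                         math.log(p.ka), math.log(p.Vc), math.log(p.CL)])

    def unpack(x: np.ndarray) -> SystemicParams:
        return SystemicParams(
            tlag=lo + span / (1.0 + math.exp(-x[0])),
            ka=math.exp(x[1]), Vc=math.exp(x[2]), CL=math.exp(x[3]))

    def fun(x: np.ndarray) -> float:
        try:
            pred = _predict_plasma(obs, phys, unpack(x), frac)
        except Exception:
            return 1e30
        return objective(obs, pred, weighting)

    x, f, ok, trace = _run_simplex(fun, pack(init), n_restarts, seed,
                                   maxiter=maxiter)
    est = unpack(x)
    n_obs = int(sum(c > 0 for c in obs.conc))
    return FitResult(
        estimates={"tlag": est.tlag, "ka": est.ka, "Vc": est.Vc, "CL": est.CL},
        objective=f, converged=ok, n_obs=n_obs, weighting=weighting,
        trace=trace, message="" if ok else "optimizer did not report convergence")


def fit_deposition(obs: ObservedSeries, phys: PhysiologyConstants,
                   sys_fixed: SystemicParams,
                   init: tuple[float, float] = (0.5, 1e-4),
                   weighting: Weighting = "1/y^2", n_restarts: int = 5,
                   seed: int = 0, maxiter: int = 600) -> FitResult:
    """Estimate (F1, F2) from a mean intranasal profile with systemic
    parameters frozen; F3..F5 fixed at 0 and F1 + F2 <= 1 enforced through
    the transform F1 = s(x1), F2 = s(x2) * (1 - F1)."""
    if obs.route != "intranasal":
        raise FittingError("fit_deposition requires an intranasal series")

    def sigmoid(z: float) -> float:
        return 1.0 / (1.0 + math.exp(-z)) if z > -500 else 0.0

    def logit(p: float) -> float:
        p = min(max(p, 1e-12), 1.0 - 1e-12)
        return math.log(p / (1.0 - p))

    def unpack(x: np.ndarray) -> DepositionFractions:
        f1 = sigmoid(x[0])
        f2 = sigmoid(x[1]) * (1.0 - f1)
        return DepositionFractions(F1=f1, F2=f2)

    def fun(x: np.ndarray) -> float:
        try:
            pred = _predict_plasma(obs, phys, sys_fixed, unpack(x))
        except Exception:
            return 1e30
        return objective(obs, pred, weighting)

    x0 = np.array([logit(init[0]), logit(init[1] / max(1.0 - init[0], 1e-12))])
    x, f, ok, trace = _run_simplex(fun, x0, n_restarts, seed, jitter=1.0,
                                   maxiter=maxiter)
    est = unpack(x)
    n_obs = int(sum(c > 0 for c in obs.conc))
    return FitResult(
        estimates={"F1": est.F1, "F2": est.F2},
        objective=f, converged=ok, n_obs=n_obs, weighting=weighting,
        trace=trace, message="" if ok else "optimizer did not report convergence")
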