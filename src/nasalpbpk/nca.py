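"""Noncompartmental analysis of concentration–time series.

Conventions: linear trapezoidal AUC; Cmax/Tmax read off the observation
grid without interpolation; terminal slope lambda_z from an unweighted
log-linear regression over the best adjusted-R^2 window among the last
3..6 points after Tmax (ties favour fewer points); AUC0-inf = AUClast +
Clast/lambda_z; CL/F and V/F are normalised by the administered device
dose.  Multidose accumulation ratios compare the final dosing interval
against the first (R_Cmax = Cmax,day7/Cmax,day1; R_AUC = AUC0-tau,day7 /
AUC0-tau,day1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np

from .model import Regimen


class NCAError(ValueError):
    """Series unusable for the requested NCA quantity."""


@dataclass
class NCAResult:
    """PK metrics; quantities that require lambda_z are NaN when the
    terminal slope cannot be estimated."""

    Cmax: float
    Tmax: float
    AUClast: float
    AUCinf: float = math.nan
    AUC_tau: float = math.nan
    AUC_pct_extrap: float = math.nan
    lambda_z: float = math.nan
    T_half: float = math.nan
    CL_F: float = math.nan
    V_F: float = math.nan
    R_Cmax: float = math.nan
    R_AUC: float = math.nan
    Cmax_first: float = math.nan  # first-interval Cmax (multidose only)
    AUC_tau_first: float = math.nan  # first-interval AUC0-tau (multidose only)
    lambda_z_n_points: int = 0
    lambda_z_adj_r2: float = math.nan

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def auc_trapezoid(times: Sequence[float], conc: Sequence[float],
                  t_start: float, t_end: float) -> float:
    """Linear trapezoidal AUC over [t_start, t_end], interpolating linearly
    at the window edges when they fall between grid nodes."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t_end <= t_start:
        raise NCAError("t_end must exceed t_start")
    if t_start < t[0] - 1e-12 or t_end > t[-1] + 1e-12:
        raise NCAError("AUC window not covered by the sampling grid")
    inside = (t > t_start) & (t < t_end)
    tt = np.concatenate([[t_start], t[inside], [t_end]])
    cc = np.concatenate([[np.interp(t_start, t, c)], c[inside],
                         [np.interp(t_end, t, c)]])
    return float(np.trapezoid(cc, tt))


def _adj_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and adjusted R^2 of an unweighted linear regression."""
    n = len(x)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return slope, adj


def lambda_z(times: Sequence[float], conc: Sequence[float]
             ) -> tuple[float, int, float]:
    """Terminal elimination rate constant (1/h).

    Searches windows of the last k points (k = 3..6) strictly after Tmax,
    excluding the Cmax point, maximising adjusted R^2 of the log-linear
    fit; exact ties resolved toward fewer points.  Raises :class:`NCAError`
    when fewer than 3 usable points exist or the best slope is
    non-negative.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    i_max = int(np.argmax(c))
    mask = (np.arange(len(t)) > i_max) & (c > 0)
    tt, cc = t[mask], np.log(c[mask])
    if len(tt) < 3:
        raise NCAError("need >= 3 positive concentrations after Tmax")
    best: tuple[float, int, float] | None = None
    for k in range(3, min(6, len(tt)) + 1):
        slope, adj = _adj_r2(tt[-k:], cc[-k:])
        if best is None or adj > best[2] + 1e-12:
            best = (-slope, k, adj)
    assert best is not None
    lam, n_pts, adj = best
    if lam <= 0 or not np.isfinite(lam):
        raise NCAError("non-positive terminal slope")
    return lam, n_pts, adj


def _terminal_block(res: NCAResult, times: np.ndarray, conc: np.ndarray,
                    dose: float) -> None:
    """Fill lambda_z-dependent metrics in place; leave NaN on failure."""
    try:
        lam, n_pts, adj = lambda_z(times, conc)
    except NCAError:
        return
    c_last = conc[conc > 0][-1]
    res.lambda_z = lam
    res.lambda_z_n_points = n_pts
    res.lambda_z_adj_r2 = adj
    res.T_half = math.log(2.0) / lam
    res.AUCinf = res.AUClast + c_last / lam
    res.AUC_pct_extrap = 100.0 * (res.AUCinf - res.AUClast) / res.AUCinf
    if dose > 0:
        res.CL_F = dose / res.AUCinf
        res.V_F = res.CL_F / lam


def nca_single_dose(times: Sequence[float], conc: Sequence[float],
                    dose: float, tau: float = 12.0) -> NCAResult:
    """NCA of a single-dose profile starting at time 0.

    ``dose`` is the administered device dose in ng (used for CL/F and V/F);
    AUClast runs to the last positive concentration.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if len(t) != len(c) or len(t) < 2:
        raise NCAError("times and conc must be equal-length with >= 2 points")
    if not np.any(c > 0):
        raise NCAError("no positive concentrations")
    i_max = int(np.argmax(c))
    pos = np.nonzero(c > 0)[0]
    t_last = t[pos[-1]]
    res = NCAResult(
        Cmax=float(c[i_max]),
        Tmax=float(t[i_max]),
        AUClast=auc_trapezoid(t, c, t[0], t_last) if t_last > t[0] else 0.0,
    )
    if t[-1] >= tau - 1e-12 and tau > t[0]:
        res.AUC_tau = auc_trapezoid(t, c, t[0], tau)
    _terminal_block(res, t, c, dose)
    return res


def nca_multidose(times: Sequence[float], conc: Sequence[float],
                  regimen: Regimen, dose: float) -> NCAResult:
    """NCA of a multidose profile: final-interval metrics plus accumulation
    ratios against the first interval.

    The first interval is [0, tau] and the final interval starts at the last
    dose time; the terminal slope comes from the post-final-dose washout.
    Reported Cmax/Tmax/AUC_tau refer to the final interval (Tmax relative to
    the final dose).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if not regimen.events:
        raise NCAError("regimen has no dose events")
    tau = regimen.tau
    t_last_dose = regimen.events[-1].time
    if t[0] > 1e-12 or t[-1] < t_last_dose + tau - 1e-12:
        raise NCAError("series must cover the first and final dosing intervals")

    in1 = (t >= -1e-12) & (t <= tau + 1e-12)
    in7 = (t >= t_last_dose - 1e-12) & (t <= t_last_dose + tau + 1e-12)
    if in1.sum() < 2 or in7.sum() < 2:
        raise NCAError("insufficient sampling within dosing intervals")
    cmax1 = float(c[in1].max())
    auc1 = auc_trapezoid(t, c, 0.0, tau)
    i7 = int(np.argmax(np.where(in7, c, -np.inf)))
    cmax7 = float(c[i7])
    auc7 = auc_trapezoid(t, c, t_last_dose, t_last_dose + tau)

    res = NCAResult(Cmax=cmax7, Tmax=float(t[i7] - t_last_dose),
                    AUClast=math.nan, AUC_tau=auc7,
                    Cmax_first=cmax1, AUC_tau_first=auc1)
    if cmax1 > 0:
        res.R_Cmax = cmax7 / cmax1
    if auc1 > 0:
        res.R_AUC = auc7 / auc1

    # washout after the final dose, clock restarted at the final dose
    wash = t >= t_last_dose - 1e-12
    tw = t[wash] - t_last_dose
    cw = c[wash]
    posw = np.nonzero(cw > 0)[0]
    if len(posw):
        res.AUClast = auc_trapezoid(tw, cw, 0.0, tw[posw[-1]]) \
            if tw[posw[-1]] > 0 else 0.0
        _terminal_block(res, tw, cw, dose)
    return res


def time_to_steady_state(times: Sequence[float], conc: Sequence[float],
                         regimen: Regimen, threshold: float = 0.95) -> int:
    """First day whose morning pre-dose trough reaches ``threshold`` times
    the final-day pre-dose trough.

    Morning doses are assumed at t = 0, 24, 48, ... h; the trough for day d
    is the concentration at t = 24*(d-1) (plasma and nasal tissue
    concentrations are continuous across dose events, so the grid value at
    the dose time is the trough).
    """
    if not 0.0 <= threshold <= 1.0:
        raise NCAError("threshold must lie in [0, 1]")
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    morning_times = sorted({ev.time for ev in regimen.events if ev.time % 24.0 == 0.0})
    troughs = []
    for tm in morning_times:
        idx = np.nonzero(np.isclose(t, tm, atol=1e-9))[0]
        if len(idx):
            troughs.append((tm, float(c[idx[0]])))
    if len(troughs) < 2:
        raise NCAError("need at least two extractable morning troughs")
    ref = troughs[-1][1]
    for tm, trough in troughs:
        if trough >= threshold * ref:
            return int(tm // 24.0) + 1
    return int(troughs[-1][0] // 24.0) + 1
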