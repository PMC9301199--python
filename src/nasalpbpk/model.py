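"""Linear compartment model of the respiratory tract coupled to a central
systemic compartment, with intranasal and oral dosing.

State layout (amounts in ng)::

    0..3   ELF of Nose, BB, bb, AL
    4..7   mucosal tissue of Nose, BB, bb, AL
    8      gastrointestinal absorbable depot
    9      central (plasma) compartment
    10     cumulative elimination (CL * Cp)
    11     cumulative unabsorbed loss: (1-FA) of GI absorption plus drug
           deposited on the non-absorbing nasal vestibule

Fluxes: ELF -> tissue is one-way diffusional clearance ``PS*fu_ELF*C_ELF``
(mucociliary clearance competes in the BB/bb segments, moving ELF contents
mouthward: bb -> BB -> pharynx -> swallowed into the GI depot); tissue and
central exchange bidirectionally, driven by the free-concentration gradient
``fu_tissue*C_tissue - fu_p*Cp`` through the same PS; the GI depot is
absorbed first-order (``ka``) with a fraction FA reaching the circulation;
elimination acts on total plasma concentration (``CL*Cp``).

An intranasal spray splits across the deposition fractions F1..F5 (nasal
ELF, pharynx, bronchial/bronchiolar/alveolar ELF); pharyngeal drug is
swallowed instantly; the remainder 1 - sum(F) lands on the keratinised
nasal vestibule and is never absorbed.  Oral doses enter the GI depot after
a lag ``tlag``.

The system is linear and time-invariant between dose events, so the default
propagator advances the state with the matrix exponential of the rate
matrix — exact to machine precision and mass-conserving by construction.
A stiff ODE path (LSODA, rtol 1e-8 / atol 1e-6 ng, hard restart at every
dose event) is available for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .physiology import SEGMENTS, PhysiologyConstants

MG_TO_NG = 1.0e6

N_STATES = 12
STATE_LABELS = (
    "ELF_Nose", "ELF_BB", "ELF_bb", "ELF_AL",
    "tissue_Nose", "tissue_BB", "tissue_bb", "tissue_AL",
    "GI", "central", "eliminated", "unabsorbed",
)
IDX = {label: i for i, label in enumerate(STATE_LABELS)}
_ELF = {seg: IDX[f"ELF_{seg}"] for seg in SEGMENTS}
_TIS = {seg: IDX[f"tissue_{seg}"] for seg in SEGMENTS}
_GI, _CENTRAL, _ELIM, _UNABS = (IDX[k] for k in ("GI", "central", "eliminated", "unabsorbed"))

Route = Literal["intranasal", "oral"]


class SimulationError(RuntimeError):
    """Integrator failure or invalid simulation state."""


@dataclass(frozen=True)
class SystemicParams:
    """Central-compartment disposition: lag (h), ka (1/h), Vc (mL), CL (mL/h).

    Peripheral exchange constants ``k12..k31`` exist for completeness and
    default (and are here fixed) to 0 — disposition beyond the respiratory
    tract is mono-compartmental.
    """

    tlag: float
    ka: float
    Vc: float
    CL: float
    k12: float = 0.0
    k21: float = 0.0
    k13: float = 0.0
    k31: float = 0.0

    def __post_init__(self) -> None:
        if self.tlag < 0:
            raise ValueError("tlag must be >= 0")
        for name in ("ka", "Vc", "CL"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("k12", "k21", "k13", "k31"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class DepositionFractions:
    """Split of an intranasal dose: F1 nasal ELF, F2 pharynx (swallowed),
    F3/F4/F5 bronchial/bronchiolar/alveolar ELF; remainder to the vestibule."""

    F1: float
    F2: float
    F3: float = 0.0
    F4: float = 0.0
    F5: float = 0.0

    def __post_init__(self) -> None:
        for name in ("F1", "F2", "F3", "F4", "F5"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.total > 1.0 + 1e-12:
            raise ValueError(f"deposition fractions sum to {self.total} > 1")

    @property
    def total(self) -> float:
        return self.F1 + self.F2 + self.F3 + self.F4 + self.F5


@dataclass(frozen=True)
class DoseEvent:
    time: float  # h
    route: Route
    amount: float  # ng

    def __post_init__(self) -> None:
        if self.time < 0 or self.amount < 0:
            raise ValueError("dose time and amount must be >= 0")
        if self.route not in ("intranasal", "oral"):
            raise ValueError(f"unknown route {self.route!r}")


@dataclass(frozen=True)
class Regimen:
    """Ordered dose events plus the reporting interval tau (h, default 12)."""

    events: tuple[DoseEvent, ...]
    tau: float = 12.0

    def __post_init__(self) -> None:
        events = tuple(self.events)
        times = [e.time for e in events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("events must be sorted by time")
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        object.__setattr__(self, "events", events)

    @classmethod
    def single_dose(cls, amount_ng: float, route: Route = "intranasal",
                    tau: float = 12.0) -> "Regimen":
        return cls(events=(DoseEvent(0.0, route, amount_ng),), tau=tau)

    @classmethod
    def bid(cls, amount_ng: float, route: Route = "intranasal", n_days: int = 7,
            interval_h: float = 12.0) -> "Regimen":
        """BID for ``n_days - 1`` full days plus a single morning dose on the
        final day (the labelled multidose design: 13 doses over 7 days)."""
        times = [24.0 * d + interval_h * j for d in range(n_days - 1) for j in (0, 1)]
        times.append(24.0 * (n_days - 1))
        times.sort()
        return cls(events=tuple(DoseEvent(t, route, amount_ng) for t in times),
                   tau=interval_h)


#: sampling offsets within each dosing interval (h post dose)
DOSE_GRID_OFFSETS = (0.0, 0.08, 0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0)
#: additional follow-up offsets after the final dose (h post final dose)
FOLLOWUP_OFFSETS = (16.0, 24.0, 36.0, 48.0, 72.0)


def default_grid(regimen: Regimen) -> np.ndarray:
    """Observation grid: the per-dose offsets after every dose plus extended
    follow-up after the final dose; duplicates merged."""
    if not regimen.events:
        return np.array([0.0])
    times = {0.0}
    for ev in regimen.events:
        times.update(ev.time + off for off in DOSE_GRID_OFFSETS)
    last = regimen.events[-1].time
    times.update(last + off for off in FOLLOWUP_OFFSETS)
    return np.array(sorted(times))


def build_rate_matrix(phys: PhysiologyConstants, sys: SystemicParams) -> np.ndarray:
    """Rate matrix M with dA/dt = M @ A.  Columns sum to zero (closed system)."""
    M = np.zeros((N_STATES, N_STATES))
    for seg in SEGMENTS:
        e, t = _ELF[seg], _TIS[seg]
        k_perm = phys.PS[seg] * phys.fu_ELF / phys.V_ELF[seg]  # ELF -> tissue
        M[e, e] -= k_perm
        M[t, e] += k_perm
        k_out = phys.PS[seg] * phys.fu_tissue / phys.V_tissue[seg]  # tissue -> central
        k_back = phys.PS[seg] * phys.fu_p / sys.Vc  # central -> tissue
        M[t, t] -= k_out
        M[_CENTRAL, t] += k_out
        M[t, _CENTRAL] += k_back
        M[_CENTRAL, _CENTRAL] -= k_back
    # mucociliary chain: bb -> BB -> pharynx (swallowed -> GI)
    M[_ELF["bb"], _ELF["bb"]] -= phys.kmcc_bb
    M[_ELF["BB"], _ELF["bb"]] += phys.kmcc_bb
    M[_ELF["BB"], _ELF["BB"]] -= phys.kmcc_BB
    M[_GI, _ELF["BB"]] += phys.kmcc_BB
    # GI absorption and systemic elimination
    M[_GI, _GI] -= sys.ka
    M[_CENTRAL, _GI] += phys.FA * sys.ka
    M[_UNABS, _GI] += (1.0 - phys.FA) * sys.ka
    k_el = sys.CL / sys.Vc
    M[_CENTRAL, _CENTRAL] -= k_el
    M[_ELIM, _CENTRAL] += k_el
    return M


def rhs(state: np.ndarray, t: float, phys: PhysiologyConstants,
        sys: SystemicParams) -> np.ndarray:
    """Time derivative of the state vector (pure function of the state)."""
    return build_rate_matrix(phys, sys) @ np.asarray(state, dtype=float)


def apply_dose(state: np.ndarray, event: DoseEvent, frac: DepositionFractions,
               phys: PhysiologyConstants) -> np.ndarray:
    """Instantaneous state update for a dose event.

    Intranasal doses split across the deposition fractions (pharyngeal drug
    swallowed straight into the GI depot, vestibule remainder booked as
    unabsorbed).  Oral doses enter the GI depot in full; the absorption lag
    is realised by :func:`simulate` scheduling the deposit at
    ``event.time + tlag``.
    """
    out = np.array(state, dtype=float)
    a = event.amount
    if event.route == "oral":
        out[_GI] += a
    else:
        out[_ELF["Nose"]] += a * frac.F1
        out[_GI] += a * frac.F2
        out[_ELF["BB"]] += a * frac.F3
        out[_ELF["bb"]] += a * frac.F4
        out[_ELF["AL"]] += a * frac.F5
        out[_UNABS] += a * (1.0 - frac.total)
    return out


@dataclass
class SimulationResult:
    """Amounts per compartment plus derived plasma and nasal concentrations.

    ``states`` has shape (len(grid), 12) in the :data:`STATE_LABELS` order;
    samples coinciding with a dose time are post-dose (plasma and nasal
    tissue concentrations are continuous across doses regardless).
    """

    grid: np.ndarray
    states: np.ndarray
    C_plasma: np.ndarray
    C_nasal: np.ndarray
    dose_admin: dict = field(default_factory=dict)
    deposited: np.ndarray | None = None  # cumulative dose in-system per grid time

    @property
    def total_administered(self) -> float:
        return float(sum(self.dose_admin.values()))

    def amounts(self, label: str) -> np.ndarray:
        return self.states[:, IDX[label]]

    def mass_balance_error(self) -> float:
        """Max deviation of total compartment mass from the cumulative
        deposited dose, relative to the total administered dose."""
        mass = self.states.sum(axis=1)
        expected = self.deposited if self.deposited is not None \
            else np.full_like(mass, self.total_administered)
        total = self.total_administered
        if total == 0:
            return float(np.max(np.abs(mass)))
        return float(np.max(np.abs(mass - expected)) / total)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: time_h, compartment, amount_ng, conc_ng_per_ml."""
        rows = []
        for j, label in enumerate(STATE_LABELS):
            conc = np.full_like(self.grid, np.nan)
            if label == "central":
                conc = self.C_plasma
            elif label == "tissue_Nose":
                conc = self.C_nasal
            rows.append(pd.DataFrame({
                "time_h": self.grid,
                "compartment": label,
                "amount_ng": self.states[:, j],
                "conc_ng_per_ml": conc,
            }))
        return pd.concat(rows, ignore_index=True)


def _deposits(regimen: Regimen, frac: DepositionFractions, sys: SystemicParams,
              phys: PhysiologyConstants) -> list[tuple[float, DoseEvent]]:
    """Expand dose events into (effective time, event) deposits; oral deposits
    are shifted by the absorption lag."""
    out = []
    for ev in regimen.events:
        t_eff = ev.time + sys.tlag if ev.route == "oral" else ev.time
        out.append((t_eff, ev))
    out.sort(key=lambda p: p[0])
    return out


def simulate(phys: PhysiologyConstants, sys: SystemicParams,
             frac: DepositionFractions, regimen: Regimen,
             grid: Sequence[float] | None = None,
             method: Literal["expm", "lsoda"] = "expm") -> SimulationResult:
    """Integrate the model over ``grid`` with dose discontinuities applied.

    The grid must be strictly increasing; the default grid covers every dose
    plus extended follow-up.  Mass balance (sum of all compartments plus
    cumulative sinks == total administered) holds to machine precision on the
    expm path and within integrator tolerance on the lsoda path.
    """
    grid = default_grid(regimen) if grid is None else np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be non-empty and strictly increasing")

    deposits = _deposits(regimen, frac, sys, phys)
    M = build_rate_matrix(phys, sys)
    propagator_cache: dict[float, np.ndarray] = {}

    def step(state: np.ndarray, dt: float) -> np.ndarray:
        if dt == 0.0:
            return state
        if method == "expm":
            P = propagator_cache.get(dt)
            if P is None:
                P = expm(M * dt)
                propagator_cache[dt] = P
            return P @ state
        sol = solve_ivp(lambda t, y: M @ y, (0.0, dt), state, method="LSODA",
                        rtol=1e-8, atol=1e-6)
        if not sol.success:
            raise SimulationError(f"LSODA failed after dt={dt}: {sol.message}")
        return sol.y[:, -1]

    # breakpoints: all grid times and deposit times, processed in order
    dep_times = np.array([t for t, _ in deposits])
    checkpoints = (np.unique(np.concatenate([grid, dep_times]))
                   if len(dep_times) else grid)

    state = np.zeros(N_STATES)
    out = np.zeros((len(grid), N_STATES))
    deposited = np.zeros(len(grid))
    in_system = 0.0
    t_cur = float(checkpoints[0])
    gi = 0
    di = 0
    for t_next in checkpoints:
        t_next = float(t_next)
        if t_next > t_cur:
            state = step(state, t_next - t_cur)
            t_cur = t_next
        while di < len(deposits) and deposits[di][0] <= t_cur + 1e-12:
            _, ev = deposits[di]
            state = apply_dose(state, ev, frac, phys)
            in_system += ev.amount
            di += 1
        while gi < len(grid) and grid[gi] <= t_cur + 1e-12:
            out[gi] = state
            deposited[gi] = in_system
            gi += 1

    if np.min(out) < -1e-3:
        raise SimulationError(f"negative compartment amount {np.min(out):.3g} ng")
    dose_admin: dict[str, float] = {}
    for ev in regimen.events:
        dose_admin[ev.route] = dose_admin.get(ev.route, 0.0) + ev.amount
    C_plasma = np.clip(out[:, _CENTRAL] / sys.Vc, 0.0, None)
    C_nasal = np.clip(out[:, _TIS["Nose"]] / phys.V_tissue["Nose"], 0.0, None)
    result = SimulationResult(grid=grid, states=out, C_plasma=C_plasma,
                              C_nasal=C_nasal, dose_admin=dose_admin,
                              deposited=deposited)
    if regimen.events and result.mass_balance_error() > 1e-3:
        raise SimulationError(
            f"mass balance violated: {result.mass_balance_error():.3g} relative")
    return result


def superpose_check(phys: PhysiologyConstants, sys: SystemicParams,
                    frac: DepositionFractions, single: Regimen,
                    multi: Regimen) -> float:
    """Max relative deviation between a multidose plasma profile and the sum
    of time-shifted single-dose profiles.  The model is linear, so this is an
    integrator audit: it must vanish (< 1e-6 relative to Cmax)."""
    if len(single.events) != 1:
        raise ValueError("single regimen must contain exactly one dose")
    grid = default_grid(multi)
    ref = simulate(phys, sys, frac, multi, grid)
    total = np.zeros_like(ref.C_plasma)
    base = single.events[0]
    for ev in multi.events:
        mask = grid >= ev.time - 1e-12
        dts = np.clip(grid[mask] - ev.time, 0.0, None)
        sub_grid = np.unique(dts)
        if sub_grid[0] != 0.0:
            sub_grid = np.concatenate([[0.0], sub_grid])
        reg = Regimen.single_dose(ev.amount, base.route, tau=single.tau)
        sub = simulate(phys, sys, frac, reg, sub_grid)
        pos = np.searchsorted(sub.grid, dts)
        total[mask] += sub.C_plasma[pos]
    cmax = ref.C_plasma.max()
    if cmax == 0:
        return float(np.max(np.abs(total)))
    return float(np.max(np.abs(ref.C_plasma - total)) / cmax)
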