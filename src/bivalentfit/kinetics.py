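"""Bivalent-analyte (1:2) binding model for SPR sensorgrams.

A bivalent analyte A (e.g. an IgG antibody) in solution binds immobilised
ligand L (antigen) in two sequential steps::

    A  + L  <-> AL1     (ka1, kd1)
    AL1 + L <-> AL2     (ka2, kd2)

All ligand species are carried in response units (RU); the analyte
concentration [A_m] is molar and held constant during the association
phase (continuous flow).  With that bookkeeping ka1 is in M^-1 s^-1 and
ka2 in RU^-1 s^-1.

Association-phase ODEs (statistical factors of two because the analyte
has two equivalent arms)::

    d[L]/dt   = -(2 ka1 [A_m][L] - kd1 [AL1]) - (ka2 [AL1][L] - 2 kd2 [AL2])
    d[AL1]/dt =  (2 ka1 [A_m][L] - kd1 [AL1]) - (ka2 [AL1][L] - 2 kd2 [AL2])
    d[AL2]/dt =                                  ka2 [AL1][L] - 2 kd2 [AL2]

Dissociation-phase ODEs assume no rebinding (ka1 = ka2 = 0)::

    d[L]/dt   =  kd1 [AL1] + 2 kd2 [AL2]
    d[AL1]/dt = -kd1 [AL1] + 2 kd2 [AL2]
    d[AL2]/dt = -2 kd2 [AL2]

Both phases conserve total ligand L + AL1 + 2*AL2.  The measured signal
is AL1 + AL2 (each bound analyte counted once).

Non-regenerative titrations start a cycle with unknown amounts of
complex left over from earlier injections.  This is handled by
back-extrapolation: the cycle is integrated from an adjusted start time
t0 = t0* - t* with a bare surface ([AL1]=[AL2]=0, [L]=Rmax), where the
initial-time adjustment t* is a per-cycle fitted parameter; only the
window from t0* onward is observed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import _fastsim
from ._fastsim import KD_DEGENERATE_TOL
from .titration_io import CyclePhases, TitrationSeries

__all__ = [
    "RateConstants", "CycleParams", "CycleDesign", "TitrationDesign",
    "association_rhs", "dissociation_rhs", "dissociation_closed_form",
    "simulate_cycle", "predict_response", "simulate_titration",
    "IntegrationError",
]

#: default integrator tolerances (relative, absolute)
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class IntegrationError(RuntimeError):
    """Numerical failure of the ODE integration (step-size collapse).

    Carries the offending parameter set in ``args`` so callers (e.g. the
    grid search) can report which start failed.
    """


def _check_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name}: non-finite value {v!r}")


@dataclass(frozen=True)
class RateConstants:
    """The four global kinetic parameters of the bivalent-analyte model.

    ka1 : M^-1 s^-1, first association rate constant
    kd1 : s^-1, first dissociation rate constant
    ka2 : RU^-1 s^-1, second (cross-arm) association rate constant
    kd2 : s^-1, second dissociation rate constant
    """

    ka1: float
    kd1: float
    ka2: float
    kd2: float

    def __post_init__(self) -> None:
        _check_finite("RateConstants", self.ka1, self.kd1, self.ka2, self.kd2)
        if min(self.ka1, self.kd1, self.ka2, self.kd2) < 0:
            raise ValueError("rate constants must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.ka1, self.kd1, self.ka2, self.kd2])


@dataclass(frozen=True)
class CycleParams:
    """Per-concentration local parameters.

    rmax  : RU, response at maximal analyte binding (proportional to the
            free-ligand level [L]_0 at the adjusted cycle start)
    tstar : s, initial-time adjustment for non-regenerative titration
    """

    rmax: float
    tstar: float = 0.0

    def __post_init__(self) -> None:
        _check_finite("CycleParams", self.rmax, self.tstar)
        if self.rmax < 0 or self.tstar < 0:
            raise ValueError("rmax and tstar must be non-negative")


@dataclass(frozen=True)
class CycleDesign:
    """Sampling design of one injection cycle.

    analyte_conc : M; t_assoc, t_dissoc : phase lengths, s;
    dt : sampling interval, s (2 s = the instrument's ~0.5 Hz);
    t0_star : nominal cycle start time t0*, s (bookkeeping only — each
    cycle is simulated on its own clock with association starting at 0).
    """

    analyte_conc: float
    t_assoc: float
    t_dissoc: float
    dt: float = 2.0
    t0_star: float = 0.0

    def __post_init__(self) -> None:
        _check_finite("CycleDesign", self.analyte_conc, self.t_assoc,
                      self.t_dissoc, self.dt)
        if self.analyte_conc < 0:
            raise ValueError("analyte_conc must be non-negative")
        if self.t_assoc <= 0 or self.t_dissoc <= 0 or self.dt <= 0:
            raise ValueError("t_assoc, t_dissoc and dt must be positive")

    def assoc_times(self) -> np.ndarray:
        """Observed association times on the cycle clock: 0, dt, ..., t_assoc."""
        n = int(round(self.t_assoc / self.dt))
        t = np.arange(n + 1) * self.dt
        if t[-1] < self.t_assoc - 1e-9:
            t = np.append(t, self.t_assoc)
        return t

    def dissoc_offsets(self) -> np.ndarray:
        """Dissociation times as offsets from the end of association."""
        n = int(round(self.t_dissoc / self.dt))
        t = np.arange(1, n + 1) * self.dt
        if t.size == 0 or t[-1] < self.t_dissoc - 1e-9:
            t = np.append(t, self.t_dissoc)
        return t


@dataclass(frozen=True)
class TitrationDesign:
    """Ordered cycle designs (low to high concentration) plus the
    regenerative flag.  Non-regenerative titrations must inject in
    strictly increasing concentration order."""

    cycles: tuple[CycleDesign, ...]
    regenerative: bool = False

    def __init__(self, cycles: Sequence[CycleDesign], regenerative: bool = False):
        object.__setattr__(self, "cycles", tuple(cycles))
        object.__setattr__(self, "regenerative", bool(regenerative))
        if len(self.cycles) == 0:
            raise ValueError("TitrationDesign needs at least one cycle")
        if not self.regenerative:
            conc = [c.analyte_conc for c in self.cycles]
            if any(b <= a for a, b in zip(conc, conc[1:])):
                raise ValueError(
                    "non-regenerative titration requires strictly "
                    "increasing analyte concentrations")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c.analyte_conc for c in self.cycles])


# ---------------------------------------------------------------------------
# right-hand sides (full 3-state form, used by the scipy reference route)

def association_rhs(state, k: RateConstants, analyte_conc: float):
    """(dL/dt, dAL1/dt, dAL2/dt) during the association phase.

    ``state`` is (L, AL1, AL2) in RU.  The derivative sums to zero under
    the weighting L + AL1 + 2*AL2 (ligand-site conservation).
    """
    L, al1, al2 = (float(s) for s in state)
    _check_finite("association_rhs state", L, al1, al2)
    _check_finite("association_rhs analyte_conc", analyte_conc)
    if analyte_conc < 0:
        raise ValueError("analyte_conc must be non-negative")
    f1 = 2.0 * k.ka1 * analyte_conc * L - k.kd1 * al1
    f2 = k.ka2 * al1 * L - 2.0 * k.kd2 * al2
    return (-f1 - f2, f1 - f2, f2)


def dissociation_rhs(state, k: RateConstants):
    """(dL/dt, dAL1/dt, dAL2/dt) during dissociation (no rebinding)."""
    L, al1, al2 = (float(s) for s in state)
    _check_finite("dissociation_rhs state", L, al1, al2)
    return (k.kd1 * al1 + 2.0 * k.kd2 * al2,
            -k.kd1 * al1 + 2.0 * k.kd2 * al2,
            -2.0 * k.kd2 * al2)


def dissociation_closed_form(initial, k: RateConstants, t) -> np.ndarray:
    """Exact solution of the linear dissociation system.

    ``initial`` is the state (L0, AL1_0, AL2_0); ``t`` a scalar or array
    of non-negative times.  Returns states with shape (len(t), 3); free
    ligand is recovered from conservation.  Near the kd1 = 2*kd2
    resonance (within ``KD_DEGENERATE_TOL``) the confluent limit branch
    is used.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    L0, al1_0, al2_0 = (float(s) for s in initial)
    al1, al2 = _fastsim.dissociate_closed(al1_0, al2_0, k.kd1, k.kd2, t)
    total = L0 + al1_0 + 2.0 * al2_0
    L = total - al1 - 2.0 * al2
    return np.column_stack([L, al1, al2])


# ---------------------------------------------------------------------------
# simulation

def _scipy_cycle(k, cp, cd, rtol, atol):
    """Reference route: full 3-state solve_ivp for both phases."""
    t_a = cd.assoc_times()
    t_d = cd.dissoc_offsets()
    y0 = [cp.rmax, 0.0, 0.0]

    def f_assoc(t, y):
        f1 = 2.0 * k.ka1 * cd.analyte_conc * y[0] - k.kd1 * y[1]
        f2 = k.ka2 * y[1] * y[0] - 2.0 * k.kd2 * y[2]
        return (-f1 - f2, f1 - f2, f2)

    sol_a = solve_ivp(f_assoc, (-cp.tstar, t_a[-1]), y0, t_eval=t_a,
                      rtol=rtol, atol=atol, method="LSODA")
    if not sol_a.success:
        raise IntegrationError("association integration failed", k, cp, cd)

    def f_diss(t, y):
        return (k.kd1 * y[1] + 2.0 * k.kd2 * y[2],
                -k.kd1 * y[1] + 2.0 * k.kd2 * y[2],
                -2.0 * k.kd2 * y[2])

    sol_d = solve_ivp(f_diss, (0.0, t_d[-1]), sol_a.y[:, -1], t_eval=t_d,
                      rtol=rtol, atol=atol, method="LSODA")
    if not sol_d.success:
        raise IntegrationError("dissociation integration failed", k, cp, cd)
    return t_a, sol_a.y.T, t_d, sol_d.y.T


def simulate_cycle(k: RateConstants, cp: CycleParams, cd: CycleDesign,
                   rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                   method: str = "fast"):
    """Simulate one injection cycle.

    The association phase is integrated from the adjusted start
    t0 = -tstar (cycle clock) with a bare surface (L=rmax), and observed
    on [0, t_assoc]; the dissociation phase continues from the
    association endpoint for t_dissoc seconds.

    Returns ``(time, phase, states)`` where ``time`` is the cycle clock,
    ``phase`` a string array ('association'/'dissociation') and
    ``states`` an (n, 3) array of (L, AL1, AL2) in RU.

    method : 'fast' (compiled RK45 on the conservation-reduced system +
    exact dissociation) or 'scipy' (full 3-state LSODA reference route).
    """
    t_a = cd.assoc_times()
    t_d = cd.dissoc_offsets()
    if method == "scipy":
        t_a, st_a, t_d, st_d = _scipy_cycle(k, cp, cd, rtol, atol)
    elif method == "fast":
        a1, a2 = _fastsim.integrate_association(
            k.ka1, k.kd1, k.ka2, k.kd2, cd.analyte_conc, cp.rmax, cp.tstar,
            t_a, rtol, atol)
        if not np.all(np.isfinite(a1)):
            raise IntegrationError("association integration failed", k, cp, cd)
        d1, d2 = _fastsim.dissociate_closed(a1[-1], a2[-1], k.kd1, k.kd2, t_d)
        L_a = cp.rmax - a1 - 2.0 * a2
        L_d = cp.rmax - d1 - 2.0 * d2
        st_a = np.column_stack([L_a, a1, a2])
        st_d = np.column_stack([L_d, d1, d2])
    else:
        raise ValueError(f"unknown method {method!r}")
    time = np.concatenate([t_a, t_a[-1] + t_d])
    phase = np.concatenate([
        np.full(t_a.size, "association"),
        np.full(t_d.size, "dissociation"),
    ])
    return time, phase, np.vstack([st_a, st_d])


def predict_response(states: np.ndarray) -> np.ndarray:
    """Measured SPR response: AL1 + AL2 per timepoint (each bound analyte
    contributes once, whether held by one arm or two)."""
    states = np.atleast_2d(np.asarray(states, dtype=float))
    return states[:, 1] + states[:, 2]


def simulate_titration(k: RateConstants, cps: Sequence[CycleParams],
                       td: TitrationDesign,
                       rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                       method: str = "fast") -> TitrationSeries:
    """Noiseless model sensorgram for a full titration.

    One ``CycleParams`` per cycle.  In regenerative mode the surface is
    stripped between cycles, so tstar is forced to 0 and every cycle
    starts from zero complexes (which the per-cycle simulation does
    anyway — regeneration simply removes the back-extrapolation).
    """
    if len(cps) != len(td.cycles):
        raise ValueError(
            f"{len(cps)} CycleParams for {len(td.cycles)} cycles")
    cycles = []
    for cp, cd in zip(cps, td.cycles):
        if td.regenerative:
            cp = CycleParams(rmax=cp.rmax, tstar=0.0)
        time, phase, states = simulate_cycle(k, cp, cd, rtol, atol, method)
        cycles.append(CyclePhases(
            analyte_conc=cd.analyte_conc,
            time=time,
            response=predict_response(states),
            phase=phase,
        ))
    return TitrationSeries(cycles=cycles)
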