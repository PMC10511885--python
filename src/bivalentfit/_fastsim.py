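"""Compiled integration kernels for the bivalent-analyte model.

The association-phase ODE system conserves total ligand
``L + AL1 + 2*AL2``, so the solver integrates only the two complex
species (AL1, AL2) and recovers free ligand algebraically; conservation
then holds to machine precision by construction.  The dissociation-phase
system is linear with constant coefficients and is evaluated through its
closed-form solution (see :func:`bivalentfit.kinetics.dissociation_closed_form`).

Everything here is numba-compiled and operates on scalars/1-D arrays;
the public API lives in :mod:`bivalentfit.kinetics`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# degenerate-branch switch for the dissociation closed form
KD_DEGENERATE_TOL = 1e-12
# step budget per cycle; exceeding it signals numerical failure (NaN).
# Physically plausible parameter regions need O(10^2-10^3) steps; only
# degenerate compensation regimes (enormous Rmax with a fast cross-arm
# rate, a stiff combination far from any data-supported optimum) exceed
# this, and failing fast there keeps the optimiser out of them.
MAX_STEPS = 4_000


@njit(cache=True)
def _assoc_f(al1, al2, ka1, kd1, ka2, kd2, am, total):
    """Reduced association RHS; free ligand from conservation."""
    lig = total - al1 - 2.0 * al2
    f1 = 2.0 * ka1 * am * lig - kd1 * al1
    f2 = ka2 * al1 * lig - 2.0 * kd2 * al2
    return f1 - f2, f2


@njit(cache=True)
def integrate_association(ka1, kd1, ka2, kd2, am, rmax, tstar,
                          t_eval, rtol, atol):
    """Adaptive Dormand–Prince RK45 from t = -tstar with (AL1,AL2)=(0,0).

    ``t_eval`` must be non-decreasing and >= -tstar.  Returns (AL1, AL2)
    sampled exactly at ``t_eval`` (integration stops at each output time,
    so outputs are solution values, not interpolants).
    """
    n = t_eval.shape[0]
    out1 = np.empty(n)
    out2 = np.empty(n)
    t = -tstar
    y1 = 0.0
    y2 = 0.0
    h = 1.0
    # Dormand-Prince 5(4) tableau
    a21 = 1.0 / 5.0
    a31 = 3.0 / 40.0; a32 = 9.0 / 40.0
    a41 = 44.0 / 45.0; a42 = -56.0 / 15.0; a43 = 32.0 / 9.0
    a51 = 19372.0 / 6561.0; a52 = -25360.0 / 2187.0
    a53 = 64448.0 / 6561.0; a54 = -212.0 / 729.0
    a61 = 9017.0 / 3168.0; a62 = -355.0 / 33.0; a63 = 46732.0 / 5247.0
    a64 = 49.0 / 176.0; a65 = -5103.0 / 18656.0
    b1 = 35.0 / 384.0; b3 = 500.0 / 1113.0; b4 = 125.0 / 192.0
    b5 = -2187.0 / 6784.0; b6 = 11.0 / 84.0
    e1 = 71.0 / 57600.0; e3 = -71.0 / 16695.0; e4 = 71.0 / 1920.0
    e5 = -17253.0 / 339200.0; e6 = 22.0 / 525.0; e7 = -1.0 / 40.0

    n_steps = 0
    for k in range(n):
        tt = t_eval[k]
        while t < tt:
            n_steps += 1
            if n_steps > MAX_STEPS:
                out1[:] = np.nan
                out2[:] = np.nan
                return out1, out2
            hh = h if t + h <= tt else tt - t
            if hh < 1e-14:
                t = tt
                break
            k11, k12 = _assoc_f(y1, y2, ka1, kd1, ka2, kd2, am, rmax)
            k21, k22 = _assoc_f(y1 + hh * a21 * k11,
                                y2 + hh * a21 * k12,
                                ka1, kd1, ka2, kd2, am, rmax)
            k31, k32 = _assoc_f(y1 + hh * (a31 * k11 + a32 * k21),
                                y2 + hh * (a31 * k12 + a32 * k22),
                                ka1, kd1, ka2, kd2, am, rmax)
            k41, k42 = _assoc_f(y1 + hh * (a41 * k11 + a42 * k21 + a43 * k31),
                                y2 + hh * (a41 * k12 + a42 * k22 + a43 * k32),
                                ka1, kd1, ka2, kd2, am, rmax)
            k51, k52 = _assoc_f(
                y1 + hh * (a51 * k11 + a52 * k21 + a53 * k31 + a54 * k41),
                y2 + hh * (a51 * k12 + a52 * k22 + a53 * k32 + a54 * k42),
                ka1, kd1, ka2, kd2, am, rmax)
            k61, k62 = _assoc_f(
                y1 + hh * (a61 * k11 + a62 * k21 + a63 * k31
                           + a64 * k41 + a65 * k51),
                y2 + hh * (a61 * k12 + a62 * k22 + a63 * k32
                           + a64 * k42 + a65 * k52),
                ka1, kd1, ka2, kd2, am, rmax)
            ny1 = y1 + hh * (b1 * k11 + b3 * k31 + b4 * k41
                             + b5 * k51 + b6 * k61)
            ny2 = y2 + hh * (b1 * k12 + b3 * k32 + b4 * k42
                             + b5 * k52 + b6 * k62)
            k71, k72 = _assoc_f(ny1, ny2, ka1, kd1, ka2, kd2, am, rmax)
            err1 = hh * (e1 * k11 + e3 * k31 + e4 * k41 + e5 * k51
                         + e6 * k61 + e7 * k71)
            err2 = hh * (e1 * k12 + e3 * k32 + e4 * k42 + e5 * k52
                         + e6 * k62 + e7 * k72)
            sc1 = atol + rtol * max(abs(y1), abs(ny1))
            sc2 = atol + rtol * max(abs(y2), abs(ny2))
            errn = np.sqrt(0.5 * ((err1 / sc1) ** 2 + (err2 / sc2) ** 2))
            if not np.isfinite(errn):
                # step blew up: shrink hard; signal failure if h collapses
                h = hh * 0.1
                if h < 1e-12:
                    out1[:] = np.nan
                    out2[:] = np.nan
                    return out1, out2
                continue
            if errn <= 1.0:
                t = t + hh
                y1 = ny1
                y2 = ny2
                fac = 2.0 if errn == 0.0 else min(2.0, max(0.2, 0.9 * errn ** -0.2))
                h = hh * fac
            else:
                h = hh * max(0.2, 0.9 * errn ** -0.2)
                if h < 1e-12:
                    out1[:] = np.nan
                    out2[:] = np.nan
                    return out1, out2
        out1[k] = y1
        out2[k] = y2
    return out1, out2


@njit(cache=True)
def dissociate_closed(al1_0, al2_0, kd1, kd2, t):
    """Closed-form (AL1, AL2) of the no-rebinding dissociation system.

    General branch requires kd1 != 2*kd2; within KD_DEGENERATE_TOL of that
    resonance the confluent limit (t * exp) branch is used.
    """
    n = t.shape[0]
    al1 = np.empty(n)
    al2 = np.empty(n)
    for i in range(n):
        ti = t[i]
        e2 = np.exp(-2.0 * kd2 * ti)
        e1 = np.exp(-kd1 * ti)
        al2[i] = al2_0 * e2
        if abs(kd1 - 2.0 * kd2) < KD_DEGENERATE_TOL:
            al1[i] = al1_0 * e1 + 2.0 * kd2 * al2_0 * ti * e1
        else:
            al1[i] = al1_0 * e1 + 2.0 * kd2 * al2_0 * (e2 - e1) / (kd1 - 2.0 * kd2)
    return al1, al2


@njit(cache=True)
def cycle_response(ka1, kd1, ka2, kd2, am, rmax, tstar,
                   t_assoc, t_dissoc_off, rtol, atol):
    """Model response AL1+AL2 for one titration cycle.

    ``t_assoc``: observed association times on the cycle clock (0-based);
    ``t_dissoc_off``: dissociation times as offsets from the end of
    association.  The association endpoint state seeds the dissociation
    closed form.  Returns (resp_assoc, resp_dissoc).
    """
    a1, a2 = integrate_association(ka1, kd1, ka2, kd2, am, rmax, tstar,
                                   t_assoc, rtol, atol)
    resp_a = a1 + a2
    n_a = t_assoc.shape[0]
    if n_a > 0:
        d1, d2 = dissociate_closed(a1[n_a - 1], a2[n_a - 1], kd1, kd2,
                                   t_dissoc_off)
    else:
        d1, d2 = dissociate_closed(0.0, 0.0, kd1, kd2, t_dissoc_off)
    return resp_a, d1 + d2
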