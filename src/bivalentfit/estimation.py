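"""Global nonlinear least-squares estimation for the bivalent-analyte model.

All M fitted concentration series share the four kinetic rate constants
(the global parameters); each series additionally carries two local
parameters, Rmax_j and the initial-time adjustment t*_j (t* dropped when
the titration is regenerative).  The objective is the unweighted sum of
squared residuals between the model response AL1+AL2 and the observed
RU, evaluated at the observed timepoints only::

    SSE(p) = sum_j sum_i ( RU_hat(p, t_i, [A_m]_j) - RU^o_{i,j} )^2

Minimisation uses a damped least-squares trust-region method
(``scipy.optimize.least_squares``, method='trf') with every parameter
bounded below by zero; on interior solutions this coincides with the
Levenberg–Marquardt minimiser.  Because the objective has local minima,
:func:`grid_search` launches the fit from a Cartesian grid of initial
guesses for the kinetic parameters (3 values per parameter by default,
3^4 = 81 starts) and keeps the best.

Parameter packing order (stable, documented): ``[ka1, kd1, ka2, kd2,
rmax_1, (tstar_1,) rmax_2, (tstar_2,) ...]`` — 4 + 2*M entries
(4 + M when regenerative), i.e. 14 when M = 5.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from . import _fastsim
from .kinetics import CycleParams, IntegrationError, RateConstants
from .titration_io import FitConfig, TitrationSeries

__all__ = [
    "ParameterVector", "FitResult", "GridSearchResult",
    "sse", "fit_global", "grid_search", "estimate_sigma",
    "default_local_init",
]

GLOBAL_NAMES = ("ka1", "kd1", "ka2", "kd2")
#: starts whose SSE is within this relative tolerance of the best are
#: labelled "global" (reached the global minimum)
GLOBAL_LABEL_RTOL = 1e-4
#: relative finite-difference step for the least-squares Jacobian; large
#: enough to stay above the ODE-integration error floor
DIFF_STEP = 1e-5
_FAIL_RESIDUAL = 1e8


@dataclass(frozen=True)
class ParameterVector:
    """Global rate constants plus per-cycle local parameters."""

    globals_: RateConstants
    locals_: tuple[CycleParams, ...]
    regenerative: bool = False

    def __init__(self, globals_, locals_, regenerative=False):
        object.__setattr__(self, "globals_", globals_)
        object.__setattr__(self, "locals_", tuple(locals_))
        object.__setattr__(self, "regenerative", bool(regenerative))
        if not self.locals_:
            raise ValueError("ParameterVector needs >=1 CycleParams")

    @property
    def n_cycles(self) -> int:
        return len(self.locals_)

    @property
    def n_params(self) -> int:
        return 4 + (1 if self.regenerative else 2) * self.n_cycles

    def names(self) -> list[str]:
        out = list(GLOBAL_NAMES)
        for j in range(1, self.n_cycles + 1):
            out.append(f"rmax_{j}")
            if not self.regenerative:
                out.append(f"tstar_{j}")
        return out

    def to_array(self) -> np.ndarray:
        vals = list(self.globals_.as_array())
        for cp in self.locals_:
            vals.append(cp.rmax)
            if not self.regenerative:
                vals.append(cp.tstar)
        return np.array(vals)

    @classmethod
    def from_array(cls, x: np.ndarray, n_cycles: int,
                   regenerative: bool = False) -> "ParameterVector":
        x = np.asarray(x, dtype=float)
        expected = 4 + (1 if regenerative else 2) * n_cycles
        if x.size != expected:
            raise ValueError(f"expected {expected} entries, got {x.size}")
        k = RateConstants(*x[:4])
        locs = []
        step = 1 if regenerative else 2
        for j in range(n_cycles):
            base = 4 + step * j
            rmax = x[base]
            tstar = 0.0 if regenerative else x[base + 1]
            locs.append(CycleParams(rmax=rmax, tstar=tstar))
        return cls(k, locs, regenerative)


@dataclass
class FitResult:
    """One converged (or flagged non-converged) local least-squares fit."""

    estimate: ParameterVector
    sse: float
    converged: bool
    n_iter: int
    start: ParameterVector
    standard_errors: np.ndarray
    message: str = ""

    @property
    def rate_constants(self) -> RateConstants:
        return self.estimate.globals_


@dataclass
class GridSearchResult:
    """All per-start fits, the best one, and local/global labels."""

    fits: list[FitResult]
    starts: list[ParameterVector]
    best_index: int
    labels: list[str] = field(default_factory=list)

    @property
    def best(self) -> FitResult:
        return self.fits[self.best_index]

    def __post_init__(self):
        if not self.labels:
            b = self.best.sse
            self.labels = [
                "global" if f.sse <= b * (1.0 + GLOBAL_LABEL_RTOL) else "local"
                for f in self.fits
            ]


# ---------------------------------------------------------------------------
# residuals

class _CycleData:
    """Precomputed per-cycle arrays for fast residual evaluation.

    Times are normalised to the cycle clock: association offsets are
    relative to the first association timestamp, dissociation offsets to
    the last association timestamp (shift-invariant).
    """

    __slots__ = ("conc", "t_assoc", "t_dissoc_off", "obs", "n_assoc")

    def __init__(self, cycle):
        am = cycle.assoc_mask
        dm = cycle.dissoc_mask
        if am.sum() < 2:
            raise ValueError("cycle needs >=2 association points to fit")
        t0 = cycle.time[am][0]
        t_end = cycle.time[am][-1]
        self.conc = float(cycle.analyte_conc)
        self.t_assoc = np.ascontiguousarray(cycle.time[am] - t0)
        self.t_dissoc_off = np.ascontiguousarray(cycle.time[dm] - t_end)
        self.obs = np.concatenate([cycle.response[am], cycle.response[dm]])
        self.n_assoc = int(am.sum())


def _prepare(series: TitrationSeries) -> list[_CycleData]:
    return [_CycleData(c) for c in series.cycles]


def _model_responses(x, cycles, regenerative, rtol, atol):
    """Model response per cycle for packed parameters ``x``; returns the
    concatenated response vector or None on integration failure."""
    ka1, kd1, ka2, kd2 = x[:4]
    step = 1 if regenerative else 2
    out = []
    for j, cd in enumerate(cycles):
        base = 4 + step * j
        rmax = x[base]
        tstar = 0.0 if regenerative else x[base + 1]
        ra, rd = _fastsim.cycle_response(
            ka1, kd1, ka2, kd2, cd.conc, rmax, tstar,
            cd.t_assoc, cd.t_dissoc_off, rtol, atol)
        if not np.all(np.isfinite(ra)) or not np.all(np.isfinite(rd)):
            return None
        out.append(ra)
        out.append(rd)
    return np.concatenate(out)


def sse(p: ParameterVector, series: TitrationSeries,
        rtol: float = 1e-8, atol: float = 1e-10) -> float:
    """Sum of squared residuals of ``p`` against the observed series."""
    cycles = _prepare(series)
    if len(cycles) != p.n_cycles:
        raise ValueError(
            f"{p.n_cycles} cycle parameter sets for {len(cycles)} cycles")
    x = p.to_array()
    model = _model_responses(x, cycles, p.regenerative, rtol, atol)
    if model is None:
        raise IntegrationError("model evaluation failed", p)
    obs = np.concatenate([c.obs for c in cycles])
    return float(np.sum((model - obs) ** 2))


def default_local_init(series: TitrationSeries,
                       cfg: FitConfig) -> tuple[CycleParams, ...]:
    """Scale-aware local-parameter starting values: rmax_j = factor x
    the cycle's maximum observed response (factor 2 by default, so the
    surface is assumed at most half-saturated); t*_j = 0 (regenerative)
    or a fixed offset (60 s default)."""
    tstar0 = 0.0 if cfg.regenerative else cfg.tstar_init
    return tuple(
        CycleParams(rmax=cfg.rmax_init_factor * float(np.max(c.response)),
                    tstar=tstar0)
        for c in series.cycles)


def fit_global(series: TitrationSeries, start: ParameterVector,
               cfg: FitConfig | None = None,
               fixed: dict[int, float] | None = None) -> FitResult:
    """Bounded trust-region least-squares fit from one starting point.

    ``fixed`` clamps packed-parameter indices to given values (used by
    the profile likelihood); clamped entries are excluded from the free
    vector and get NaN standard errors.  Non-convergence within the
    iteration budget is reported on the result, not raised.
    """
    cfg = cfg or FitConfig()
    cycles = _prepare(series)
    if len(cycles) != start.n_cycles:
        raise ValueError(
            f"{start.n_cycles} cycle parameter sets for {len(cycles)} cycles")
    regen = start.regenerative
    x_full = start.to_array()
    n = x_full.size
    fixed = dict(fixed or {})
    for i, v in fixed.items():
        x_full[i] = v
    free = np.array([i for i in range(n) if i not in fixed], dtype=int)
    if free.size == 0:
        raise ValueError("no free parameters")
    if np.any(x_full < 0):
        raise ValueError("start must satisfy the lower bounds (>= 0)")
    obs = np.concatenate([c.obs for c in cycles])

    def residuals(x_free):
        x = x_full.copy()
        x[free] = x_free
        model = _model_responses(x, cycles, regen, cfg.rtol, cfg.atol)
        if model is None:
            return np.full(obs.size, _FAIL_RESIDUAL)
        return model - obs

    with np.errstate(all="ignore"):  # trf emits benign overflow warnings
        res = least_squares(
            residuals, x_full[free], bounds=(0.0, np.inf), method="trf",
            x_scale="jac", diff_step=DIFF_STEP,
            ftol=cfg.ftol, gtol=cfg.gtol, xtol=None, max_nfev=cfg.max_nfev)

    x_hat = x_full.copy()
    x_hat[free] = res.x
    est = ParameterVector.from_array(x_hat, len(cycles), regen)
    fit_sse = float(2.0 * res.cost)
    bse = np.full(n, np.nan)
    dof = obs.size - free.size
    if dof > 0 and np.all(np.isfinite(res.jac)):
        # Jacobian-based covariance approximation: s^2 (J'J)^-1
        s2 = fit_sse / dof
        jtj = res.jac.T @ res.jac
        try:
            cov = s2 * np.linalg.pinv(jtj)
            bse[free] = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            pass
    return FitResult(
        estimate=est,
        sse=fit_sse,
        converged=bool(res.status > 0),
        n_iter=int(res.nfev),
        start=start,
        standard_errors=bse,
        message=str(res.message),
    )


def _make_starts(series: TitrationSeries, cfg: FitConfig
                 ) -> list[ParameterVector]:
    axes = [cfg.grid[name] for name in GLOBAL_NAMES]
    for name, axis in zip(GLOBAL_NAMES, axes):
        if len(axis) == 0:
            raise ValueError(f"empty grid axis {name!r}")
    locs = default_local_init(series, cfg)
    starts = []
    for combo in itertools.product(*axes):
        starts.append(ParameterVector(
            RateConstants(*combo), locs, cfg.regenerative))
    return starts


def grid_search(series: TitrationSeries,
                cfg: FitConfig | None = None) -> GridSearchResult:
    """Run :func:`fit_global` from every Cartesian combination of the
    configured initial-value axes (81 starts by default) and keep the
    lowest-SSE fit.  Per-start fits are independent and deterministic,
    so the result does not depend on execution order or worker count
    (ties broken by start index)."""
    cfg = cfg or FitConfig()
    starts = _make_starts(series, cfg)
    from dataclasses import replace
    explore_cfg = replace(cfg, max_nfev=min(cfg.grid_max_nfev, cfg.max_nfev))
    if cfg.workers > 1:
        from joblib import Parallel, delayed
        fits = Parallel(n_jobs=cfg.workers)(
            delayed(fit_global)(series, s, explore_cfg) for s in starts)
    else:
        fits = [fit_global(series, s, explore_cfg) for s in starts]
    sses = np.array([f.sse for f in fits])
    best = int(np.argmin(sses))  # first minimum -> start-index tie-break
    if cfg.max_nfev > explore_cfg.max_nfev:
        # polish the winning start under the full iteration budget
        polished = fit_global(series, fits[best].estimate, cfg)
        if polished.sse <= fits[best].sse:
            polished = FitResult(
                estimate=polished.estimate, sse=polished.sse,
                converged=polished.converged,
                n_iter=fits[best].n_iter + polished.n_iter,
                start=starts[best],
                standard_errors=polished.standard_errors,
                message=polished.message)
            fits[best] = polished
    return GridSearchResult(fits=list(fits), starts=starts, best_index=best)


def estimate_sigma(best: FitResult, series: TitrationSeries) -> float:
    """Residual standard deviation sqrt(SSE / (N - #p)), used as the
    measurement-error SD in the likelihood when sigma is not given."""
    n = series.n_points
    p = best.estimate.n_params
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    return float(np.sqrt(best.sse / (n - p)))
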