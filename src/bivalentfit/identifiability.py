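"""Profile-likelihood practical-identifiability analysis.

With i.i.d. Gaussian measurement error of known SD sigma, the negative
log-likelihood of the sensorgram data is::

    NLL(p) = N/2 * ln(2*pi) + SSE(p) / (2 * sigma^2)

(the additive constant is kept so reported values are reproducible; the
minimiser is independent of it and of sigma).  The profile likelihood of
parameter p_j is the constrained minimum over the remaining parameters::

    PLL_j(c) = min { NLL(p) : p_j = c }

evaluated on a log-spaced grid of clamp values c.  A parameter is
practically identifiable when its profile rises above the confidence
threshold::

    threshold = min NLL + chi2(alpha, df) / 2

on both sides of the optimum; if the profile stays below the threshold
all the way to a grid boundary on one side, the data do not bound the
parameter on that side and it is practically non-identifiable (the
classic one-sided-flat "L-shape" profile).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .estimation import (FitResult, GLOBAL_NAMES, ParameterVector,
                         estimate_sigma, fit_global)
from .titration_io import FitConfig, TitrationSeries

__all__ = [
    "ProfileSpec", "ProfileResult", "nll", "pll_threshold",
    "profile_likelihood", "classify_identifiability", "default_profile_grid",
    "InconsistentProfileError",
]

IDENTIFIABLE = "identifiable"
NON_IDENTIFIABLE = "practically-non-identifiable"


class InconsistentProfileError(RuntimeError):
    """The whole profile lies above the threshold: the unconstrained
    optimum is not bracketed by the grid."""


def nll(p: ParameterVector, series: TitrationSeries, sigma: float,
        sse_value: float | None = None) -> float:
    """Gaussian negative log-likelihood N/2 ln(2 pi) + SSE/(2 sigma^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if sse_value is None:
        from .estimation import sse as _sse
        sse_value = _sse(p, series)
    n = series.n_points
    return 0.5 * n * np.log(2.0 * np.pi) + sse_value / (2.0 * sigma ** 2)


def pll_threshold(min_nll: float, alpha: float = 0.95, df: int = 1) -> float:
    """Confidence threshold min NLL + chi2(alpha, df)/2.

    df=1 gives per-parameter (pointwise) intervals; df = #p the joint
    threshold used when all parameters share one confidence region.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(min_nll + chi2.ppf(alpha, df) / 2.0)


@dataclass(frozen=True)
class ProfileSpec:
    """Which parameter to profile and on what grid.

    grid : ascending clamp values (>=5), in the parameter's units
    alpha : confidence level; df : 1 or the number of fitted parameters
    sigma : measurement-error SD, RU
    """

    parameter: str
    grid: np.ndarray
    alpha: float = 0.95
    df: int = 14
    sigma: float = 6.0

    def __post_init__(self):
        if self.parameter not in GLOBAL_NAMES:
            raise ValueError(f"parameter must be one of {GLOBAL_NAMES}")
        grid = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", grid)
        if grid.size < 5:
            raise ValueError("profile grid needs >= 5 points")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("profile grid must be strictly ascending")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass
class ProfileResult:
    """Profile-likelihood curve and identifiability verdict for one
    parameter.  ``ok`` flags grid points whose constrained fit
    succeeded; failures are recorded, not fatal."""

    parameter: str
    grid: np.ndarray
    pll: np.ndarray
    ok: np.ndarray
    min_nll: float
    threshold: float
    verdict: str = ""
    flat_sides: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.parameter,
            "value": self.grid,
            "pll": self.pll,
            "ok": self.ok,
            "threshold": self.threshold,
            "verdict": self.verdict,
        })

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "grid": self.grid.tolist(),
            "pll": self.pll.tolist(),
            "ok": self.ok.tolist(),
            "min_nll": self.min_nll,
            "threshold": self.threshold,
            "verdict": self.verdict,
            "flat_sides": list(self.flat_sides),
        }


def default_profile_grid(estimate: float, n_points: int = 21,
                         decades_below: float = 3.0,
                         decades_above: float = 2.0,
                         floor: float = 1e-8) -> np.ndarray:
    """Log-spaced clamp grid around an estimate: ``decades_below``
    decades below to ``decades_above`` above.  An estimate at (or
    below) the zero bound carries no scale, so the grid is instead
    anchored with its lower edge at ``floor`` and spans the same total
    number of decades upward."""
    est = float(estimate)
    if est > floor:
        lo = np.log10(est) - decades_below
        hi = np.log10(est) + decades_above
    else:
        lo = np.log10(floor)
        hi = lo + decades_below + decades_above
    return np.logspace(lo, hi, n_points)


def classify_identifiability(profile: ProfileResult,
                             min_points: int = 5) -> ProfileResult:
    """Attach the identifiability verdict to a profile.

    Identifiable iff the profile rises above the threshold on both
    sides of its minimum; a side that never crosses before the grid
    boundary is flat, making the parameter practically non-identifiable
    (flat side(s) recorded).  A profile entirely above the threshold
    means the optimum was not bracketed and is an error.
    """
    ok = profile.ok
    if ok.sum() < min_points:
        raise ValueError(f"profile needs >= {min_points} valid points")
    pll = profile.pll[ok]
    grid = profile.grid[ok]
    thr = profile.threshold
    if np.all(pll > thr):
        raise InconsistentProfileError(
            f"{profile.parameter}: entire profile above threshold")
    imin = int(np.argmin(pll))
    flat = []
    if not np.any(pll[:imin] > thr):
        flat.append("left")
    if not np.any(pll[imin + 1:] > thr):
        flat.append("right")
    profile.flat_sides = tuple(flat)
    profile.verdict = NON_IDENTIFIABLE if flat else IDENTIFIABLE
    return profile


def profile_likelihood(series: TitrationSeries, best: FitResult,
                       spec: ProfileSpec,
                       cfg: FitConfig | None = None,
                       stop_after_crossing: bool = False) -> ProfileResult:
    """Compute the profile likelihood of one kinetic parameter.

    Each grid point clamps p_j = c and re-fits all remaining parameters
    (the estimation machinery with one coordinate fixed), warm-started
    from the neighbouring grid point's constrained optimum, sweeping
    outward from the grid point nearest the unconstrained estimate.
    Constrained-fit failures flag the point and the sweep continues.

    With ``stop_after_crossing`` the outward sweep on a side ends once
    the profile has risen clearly above the threshold (margin of one
    extra chi-square step); the remaining points are left unevaluated.
    The verdict is unaffected — that side has provably crossed — but
    the returned curve is partial, so leave this off when the full
    curve is wanted.  Constrained re-fits use the looser
    ``cfg.profile_ftol`` / ``cfg.profile_max_nfev`` controls.
    """
    from dataclasses import replace
    cfg = cfg or FitConfig()
    cfg = replace(cfg, ftol=cfg.profile_ftol, max_nfev=cfg.profile_max_nfev)
    idx = GLOBAL_NAMES.index(spec.parameter)
    x_best = best.estimate.to_array()
    n_cycles = best.estimate.n_cycles
    regen = best.estimate.regenerative

    grid = spec.grid
    n = grid.size
    pll = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    best_nll = nll(best.estimate, series, spec.sigma, sse_value=best.sse)

    anchor = int(np.argmin(np.abs(np.log(np.maximum(grid, 1e-300))
                                  - np.log(max(x_best[idx], 1e-300)))))
    from scipy.stats import chi2 as _chi2
    stop_level = best_nll + _chi2.ppf(spec.alpha, spec.df)  # thr + margin

    def _sweep(indices, warm):
        for i in indices:
            x0 = warm.copy()
            x0[idx] = grid[i]
            start = ParameterVector.from_array(x0, n_cycles, regen)
            try:
                fit = fit_global(series, start, cfg, fixed={idx: grid[i]})
                pll[i] = nll(fit.estimate, series, spec.sigma,
                             sse_value=fit.sse)
                ok[i] = True
                warm = fit.estimate.to_array()
            except Exception:  # constrained-fit failure is data, not fatal
                ok[i] = False
                continue
            if stop_after_crossing and pll[i] > stop_level:
                break

    _sweep(range(anchor, n), x_best.copy())
    _sweep(range(anchor - 1, -1, -1), x_best.copy())

    min_nll = float(min(best_nll, np.nanmin(pll[ok]) if ok.any() else np.inf))
    thr = pll_threshold(min_nll, spec.alpha, spec.df)
    prof = ProfileResult(
        parameter=spec.parameter, grid=grid, pll=pll, ok=ok,
        min_nll=min_nll, threshold=thr)
    return classify_identifiability(
        prof, min_points=2 if stop_after_crossing else 5)
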