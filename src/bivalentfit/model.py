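"""Model/Results facade over the fitting and identifiability machinery.

Follows the statsmodels convention: a model object is constructed from
data (plus configuration), ``fit()`` returns a results object carrying
estimates, standard errors and diagnostics, and simulation, profiling
and summary tables hang off those two objects.

Example
-------
>>> from bivalentfit import BivalentKineticsModel, FitConfig
>>> model = BivalentKineticsModel.from_csv("titration.csv")
>>> res = model.fit()                   # 81-start grid search
>>> print(res.summary())
>>> prof = res.profile("kd2")           # profile likelihood
>>> prof.verdict
'practically-non-identifiable'
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import estimation, identifiability
from .estimation import (FitResult, GLOBAL_NAMES, GridSearchResult,
                         ParameterVector, estimate_sigma, fit_global,
                         grid_search)
from .identifiability import (ProfileResult, ProfileSpec,
                              default_profile_grid, nll, pll_threshold,
                              profile_likelihood)
from .kinetics import CycleDesign, CycleParams, TitrationDesign, simulate_titration
from .titration_io import FitConfig, TitrationSeries, read_sensorgram_csv

__all__ = ["BivalentKineticsModel", "BivalentKineticsResults"]


class BivalentKineticsModel:
    """Bivalent-analyte (1:2) kinetic model bound to a titration dataset.

    Parameters
    ----------
    series : TitrationSeries
        Observed (or synthetic) sensorgrams, one cycle per analyte
        concentration.
    config : FitConfig, optional
        Fitting/profiling configuration; ``config.concentrations``
        restricts the fit to the listed cycles (the operator-chosen
        linear range).
    """

    def __init__(self, series: TitrationSeries,
                 config: FitConfig | None = None):
        self.config = config or FitConfig()
        if self.config.concentrations:
            series = series.select(self.config.concentrations)
        self.series = series

    @classmethod
    def from_csv(cls, path, config: FitConfig | None = None):
        return cls(read_sensorgram_csv(path), config)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       config: FitConfig | None = None):
        return cls(TitrationSeries.from_frame(df), config)

    @property
    def n_cycles(self) -> int:
        return self.series.n_cycles

    @property
    def nobs(self) -> int:
        return self.series.n_points

    def fit(self, start: ParameterVector | None = None,
            method: str = "grid") -> "BivalentKineticsResults":
        """Fit the model.

        method='grid' (default) runs the initialisation grid search and
        returns results for the lowest-SSE start; method='single' runs
        one local fit from ``start`` (required).
        """
        if method == "grid":
            gs = grid_search(self.series, self.config)
            return BivalentKineticsResults(self, gs.best, grid=gs)
        if method == "single":
            if start is None:
                raise ValueError("method='single' requires a start")
            fr = fit_global(self.series, start, self.config)
            return BivalentKineticsResults(self, fr, grid=None)
        raise ValueError(f"unknown method {method!r}")


class BivalentKineticsResults:
    """Fit results: estimates, uncertainties, diagnostics and profiles."""

    def __init__(self, model: BivalentKineticsModel, fit: FitResult,
                 grid: GridSearchResult | None = None):
        self.model = model
        self.fit_result = fit
        self.grid = grid

    # -- estimates ---------------------------------------------------------
    @property
    def params(self) -> ParameterVector:
        return self.fit_result.estimate

    @property
    def rate_constants(self):
        return self.params.globals_

    @property
    def bse(self) -> np.ndarray:
        """Standard errors (Jacobian-based covariance approximation)."""
        return self.fit_result.standard_errors

    @property
    def sse(self) -> float:
        return self.fit_result.sse

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def df_resid(self) -> int:
        return self.nobs - self.params.n_params

    @property
    def sigma_hat(self) -> float:
        """Residual-SD estimate of the measurement error, RU."""
        return estimate_sigma(self.fit_result, self.model.series)

    def sigma(self) -> float:
        """Measurement-error SD used in likelihood computations: the
        configured value if numeric, else the residual-SD estimate."""
        s = self.model.config.sigma
        return float(s) if isinstance(s, (int, float)) else self.sigma_hat

    def nll(self) -> float:
        return nll(self.params, self.model.series, self.sigma(),
                   sse_value=self.sse)

    # -- predictions -------------------------------------------------------
    def predict(self) -> TitrationSeries:
        """Noiseless fitted sensorgram at the observed designs."""
        cycles = []
        dt_guess = None
        designs = []
        for c, cp in zip(self.model.series.cycles, self.params.locals_):
            t_a = c.time[c.assoc_mask]
            t_d = c.time[c.dissoc_mask]
            dt = float(np.median(np.diff(c.time[c.assoc_mask])))
            designs.append(CycleDesign(
                analyte_conc=c.analyte_conc,
                t_assoc=float(t_a[-1] - t_a[0]),
                t_dissoc=float(t_d[-1] - t_a[-1]) if t_d.size else dt,
                dt=dt))
        td = TitrationDesign(designs,
                             regenerative=self.params.regenerative)
        return simulate_titration(self.rate_constants, self.params.locals_,
                                  td)

    def resid(self) -> np.ndarray:
        obs = self.model.series.responses()
        fitted = self.predict().responses()
        n = min(obs.size, fitted.size)
        return obs[:n] - fitted[:n]

    # -- identifiability ---------------------------------------------------
    def profile(self, parameter: str, grid: np.ndarray | None = None,
                ) -> ProfileResult:
        """Profile likelihood of one kinetic parameter, with verdict."""
        cfg = self.model.config
        if grid is None:
            est = float(self.params.globals_.as_array()[
                GLOBAL_NAMES.index(parameter)])
            grid = default_profile_grid(
                est, cfg.profile_points, cfg.profile_decades_below,
                cfg.profile_decades_above, cfg.profile_floor)
        df = self.params.n_params if cfg.df == "np" else int(cfg.df)
        spec = ProfileSpec(parameter=parameter, grid=np.asarray(grid),
                           alpha=cfg.alpha, df=df, sigma=self.sigma())
        return profile_likelihood(self.model.series, self.fit_result,
                                  spec, cfg)

    def profile_all(self) -> dict[str, ProfileResult]:
        return {name: self.profile(name) for name in GLOBAL_NAMES}

    # -- reporting ---------------------------------------------------------
    def params_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.params.names(),
            "estimate": self.params.to_array(),
            "std_err": self.bse,
        })

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = []
        lines.append("Bivalent Analyte Kinetics — Global Fit")
        lines.append("=" * 54)
        lines.append(f"{'No. cycles (M):':<28}{self.model.n_cycles}")
        lines.append(f"{'No. observations:':<28}{self.nobs}")
        lines.append(f"{'No. parameters:':<28}{self.params.n_params}")
        lines.append(f"{'SSE (RU^2):':<28}{self.sse:.6g}")
        lines.append(f"{'Residual SD (RU):':<28}{self.sigma_hat:.4g}")
        lines.append(f"{'Converged:':<28}{self.converged}")
        if self.grid is not None:
            n_glob = sum(1 for lab in self.grid.labels if lab == "global")
            lines.append(f"{'Grid starts:':<28}{len(self.grid.fits)}"
                         f"  (reached global: {n_glob})")
        lines.append("-" * 54)
        lines.append(f"{'parameter':<12}{'estimate':>14}{'std err':>14}")
        units = {"ka1": "M^-1 s^-1", "kd1": "s^-1",
                 "ka2": "RU^-1 s^-1", "kd2": "s^-1"}
        for name, est, se in zip(self.params.names(),
                                 self.params.to_array(), self.bse):
            u = units.get(name, "RU" if name.startswith("rmax") else "s")
            lines.append(f"{name:<12}{est:>14.4g}{se:>14.4g}  {u}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def __repr__(self) -> str:
        k = self.rate_constants
        return (f"<BivalentKineticsResults ka1={k.ka1:.3g} kd1={k.kd1:.3g} "
                f"ka2={k.ka2:.3g} kd2={k.kd2:.3g} sse={self.sse:.4g}>")
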