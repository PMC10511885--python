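"""Synthetic titrations and simulation-guided experimental design.

The design loop mirrors how an SPR lab would vet a data-collection
scheme before spending reagent: simulate noisy sensorgrams under a
candidate design, run the full grid-search fit, profile every kinetic
parameter, and check which parameters the design actually constrains.
The bundled scenario pair contrasts the instrument's standard 600 s
dissociation window with an extended 1780 s window; the slow second
dissociation step (kd2 ~ 1e-5 s^-1) is only practically identifiable
under the latter.

Replicate dispersion is summarised by the coefficient of variation
(CV = sample SD / mean, n-1 denominator) per kinetic parameter across
replicate fits, the same summary used for experimental replicates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import (GLOBAL_NAMES, GridSearchResult, ParameterVector,
                         grid_search)
from .identifiability import (ProfileResult, ProfileSpec,
                              default_profile_grid, profile_likelihood)
from .kinetics import (CycleDesign, CycleParams, RateConstants,
                       TitrationDesign, simulate_titration)
from .titration_io import CyclePhases, FitConfig, TitrationSeries

__all__ = [
    "NoiseModel", "DesignScenario", "ReplicateSummary", "DesignReport",
    "generate_noisy_titration", "evaluate_design", "cv_across_replicates",
    "standard_scenario", "extended_scenario", "simulation_truth",
]

#: estimates at (numerically on) the zero lower bound are excluded from
#: CV summaries, mirroring the exclusion of kd2=0 fits from log-plots
ZERO_BOUND_TOL = 1e-12

#: simulation-study generating values: rate constants, shared Rmax (RU)
#: and per-cycle initial-time adjustments (s), low to high concentration
TRUTH_RATES = RateConstants(ka1=2.00e3, kd1=4.00e-3, ka2=5.00e-5, kd2=1.00e-5)
TRUTH_RMAX = 600.0
TRUTH_TSTAR = (283.0, 300.0, 282.0, 222.0, 145.0)
#: five-point doubling concentration ladder, M
CONC_LADDER = (6.25e-8, 1.25e-7, 2.5e-7, 5.0e-7, 1.0e-6)

#: coarse initialisation grid for replicated scans: the outer two of the
#: three default decade values per axis (2^4 = 16 starts), bracketing
#: the same search region at a quarter of the cost
QUICK_GRID = {
    "ka1": [1e2, 1e4],
    "kd1": [1e-4, 1e-2],
    "ka2": [1e-5, 1e-3],
    "kd2": [1e-5, 1e-3],
}
T_ASSOC = 300.0
T_DISSOC_STANDARD = 600.0
T_DISSOC_EXTENDED = 1780.0


@dataclass(frozen=True)
class NoiseModel:
    """I.i.d. Gaussian measurement noise, N(0, sigma^2), in RU."""

    sigma: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class DesignScenario:
    """A candidate data-collection scheme plus the generating truth."""

    label: str
    design: TitrationDesign
    truth: ParameterVector
    noise: NoiseModel = NoiseModel()
    n_replicates: int = 10

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if len(self.truth.locals_) != len(self.design.cycles):
            raise ValueError("truth locals must match design cycles")


def simulation_truth(regenerative: bool = False) -> ParameterVector:
    """The simulation-study generating parameter vector."""
    locs = tuple(CycleParams(rmax=TRUTH_RMAX,
                             tstar=0.0 if regenerative else t)
                 for t in TRUTH_TSTAR)
    return ParameterVector(TRUTH_RATES, locs, regenerative)


def _scenario(label: str, t_dissoc: float, sigma: float, seed: int,
              n_replicates: int, dt: float = 2.0) -> DesignScenario:
    cycles = [CycleDesign(analyte_conc=c, t_assoc=T_ASSOC,
                          t_dissoc=t_dissoc, dt=dt)
              for c in CONC_LADDER]
    return DesignScenario(
        label=label,
        design=TitrationDesign(cycles, regenerative=False),
        truth=simulation_truth(),
        noise=NoiseModel(sigma=sigma, seed=seed),
        n_replicates=n_replicates)


def standard_scenario(sigma: float = 6.0, seed: int = 0,
                      n_replicates: int = 10) -> DesignScenario:
    """300 s association / 600 s dissociation (the instrument default)."""
    return _scenario("standard", T_DISSOC_STANDARD, sigma, seed, n_replicates)


def extended_scenario(sigma: float = 6.0, seed: int = 0,
                      n_replicates: int = 10) -> DesignScenario:
    """300 s association / 1780 s extended dissociation."""
    return _scenario("extended", T_DISSOC_EXTENDED, sigma, seed, n_replicates)


def generate_noisy_titration(scenario: DesignScenario,
                             replicate_index: int = 0) -> TitrationSeries:
    """Noiseless model sensorgram plus i.i.d. Gaussian noise per
    timepoint; fully reproducible from (noise.seed, replicate_index)."""
    clean = simulate_titration(scenario.truth.globals_,
                               scenario.truth.locals_,
                               scenario.design)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(scenario.noise.seed),
                               spawn_key=(int(replicate_index),)))
    noisy = []
    for cyc in clean.cycles:
        eps = rng.normal(0.0, scenario.noise.sigma, size=cyc.response.shape)
        noisy.append(CyclePhases(
            analyte_conc=cyc.analyte_conc,
            time=cyc.time.copy(),
            response=cyc.response + eps,
            phase=cyc.phase.copy(),
        ))
    return TitrationSeries(cycles=noisy)


@dataclass
class ReplicateSummary:
    """Per-parameter dispersion of estimates across replicates."""

    values: dict[str, list[float]]
    n_excluded: dict[str, int]
    mean: dict[str, float]
    sd: dict[str, float]
    cv: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "values": self.values,
            "n_excluded": self.n_excluded,
            "mean": self.mean,
            "sd": self.sd,
            "cv": self.cv,
        }


def cv_across_replicates(estimates: Sequence[ParameterVector]
                         ) -> ReplicateSummary:
    """CV (sample SD / mean, n-1 denominator) of each kinetic parameter
    across replicate estimates.  Estimates at the zero lower bound are
    excluded and counted; a parameter with fewer than two usable values
    gets NaN mean/SD/CV (undefined)."""
    if len(estimates) < 2:
        raise ValueError("need >= 2 replicate estimates")
    values: dict[str, list[float]] = {}
    n_excl: dict[str, int] = {}
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    cv: dict[str, float] = {}
    for i, name in enumerate(GLOBAL_NAMES):
        raw = [float(p.globals_.as_array()[i]) for p in estimates]
        kept = [v for v in raw if v > ZERO_BOUND_TOL]
        values[name] = raw
        n_excl[name] = len(raw) - len(kept)
        if len(kept) >= 2:
            arr = np.array(kept)
            m = float(arr.mean())
            s = float(arr.std(ddof=1))
            mean[name] = m
            sd[name] = s
            cv[name] = s / m if m != 0 else float("nan")
        else:
            mean[name] = sd[name] = cv[name] = float("nan")
    return ReplicateSummary(values, n_excl, mean, sd, cv)


@dataclass
class DesignReport:
    """Outcome of one design evaluation: per-replicate best fits and
    profiles, aggregate (majority) verdict per parameter, and the
    replicate dispersion summary."""

    scenario_label: str
    estimates: list[ParameterVector]
    grid_results: list[GridSearchResult]
    profiles: list[dict[str, ProfileResult]]
    verdicts: dict[str, str]
    verdict_counts: dict[str, dict[str, int]]
    summary: ReplicateSummary
    failures: list[str]

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario_label,
            "n_replicates": len(self.estimates),
            "verdicts": self.verdicts,
            "verdict_counts": self.verdict_counts,
            "summary": self.summary.to_dict(),
            "estimates": [
                {name: float(v) for name, v in
                 zip(p.names(), p.to_array())}
                for p in self.estimates
            ],
            "profiles": [
                {name: pr.to_dict() for name, pr in reps.items()}
                for reps in self.profiles
            ],
            "failures": self.failures,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def evaluate_design(scenario: DesignScenario,
                    cfg: FitConfig | None = None,
                    parameters: Sequence[str] = GLOBAL_NAMES,
                    ) -> DesignReport:
    """Run the full design-evaluation loop for one scenario.

    Per replicate: generate a noisy titration, grid-search the global
    fit, profile each requested kinetic parameter and classify its
    identifiability.  Per-replicate failures are recorded in the report
    and do not abort the sweep.  Aggregate verdict per parameter is the
    majority over replicates; dispersion is the CV summary.
    """
    cfg = cfg or FitConfig()
    estimates: list[ParameterVector] = []
    grids: list[GridSearchResult] = []
    profiles: list[dict[str, ProfileResult]] = []
    failures: list[str] = []
    counts = {name: {"identifiable": 0, "practically-non-identifiable": 0}
              for name in parameters}
    for r in range(scenario.n_replicates):
        series = generate_noisy_titration(scenario, r)
        try:
            gs = grid_search(series, cfg)
        except Exception as exc:  # keep sweeping; failure is reported
            failures.append(f"replicate {r}: grid search failed: {exc}")
            continue
        best = gs.best
        estimates.append(best.estimate)
        grids.append(gs)
        sigma = (cfg.sigma if isinstance(cfg.sigma, (int, float))
                 else scenario.noise.sigma)
        reps: dict[str, ProfileResult] = {}
        df = best.estimate.n_params if cfg.df == "np" else int(cfg.df)
        for name in parameters:
            est = float(best.estimate.globals_.as_array()[
                list(GLOBAL_NAMES).index(name)])
            grid = default_profile_grid(
                est, cfg.profile_points, cfg.profile_decades_below,
                cfg.profile_decades_above, cfg.profile_floor)
            spec = ProfileSpec(parameter=name, grid=grid, alpha=cfg.alpha,
                               df=df, sigma=float(sigma))
            try:
                # verdicts only need threshold crossings, so the sweep
                # may stop once a side has clearly crossed
                prof = profile_likelihood(series, best, spec, cfg,
                                          stop_after_crossing=True)
                reps[name] = prof
                counts[name][prof.verdict] += 1
            except Exception as exc:
                failures.append(
                    f"replicate {r}: profile {name} failed: {exc}")
        profiles.append(reps)
    if len(estimates) >= 2:
        summary = cv_across_replicates(estimates)
    else:
        nan = {n: float("nan") for n in GLOBAL_NAMES}
        summary = ReplicateSummary(
            {n: [] for n in GLOBAL_NAMES},
            {n: 0 for n in GLOBAL_NAMES}, dict(nan), dict(nan), dict(nan))
    verdicts = {}
    for name in parameters:
        c = counts[name]
        total = c["identifiable"] + c["practically-non-identifiable"]
        if total == 0:
            verdicts[name] = "undetermined"
        else:
            verdicts[name] = ("identifiable"
                              if c["identifiable"] * 2 > total
                              else "practically-non-identifiable")
    return DesignReport(
        scenario_label=scenario.label,
        estimates=estimates,
        grid_results=grids,
        profiles=profiles,
        verdicts=verdicts,
        verdict_counts=counts,
        summary=summary,
        failures=failures,
    )
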