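"""Sensorgram containers and plain-text I/O.

The canonical on-disk format is a long-format, UTF-8, "."-decimal CSV
with header columns ``cycle, concentration_M, time_s, response_RU,
phase`` — one file per replicate dataset.  Vendor exports vary; convert
to this dialect upstream.  Times are on each cycle's own clock with the
association phase starting at (or near) zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CyclePhases", "TitrationSeries", "FitConfig",
    "read_sensorgram_csv", "write_sensorgram_csv", "dose_response_summary",
    "SensorgramFormatError",
]

ASSOC = "association"
DISSOC = "dissociation"
_COLUMNS = ["cycle", "concentration_M", "time_s", "response_RU", "phase"]


class SensorgramFormatError(ValueError):
    """Malformed sensorgram table (missing column, bad phase layout...)."""


@dataclass
class CyclePhases:
    """One injection cycle: times (s), responses (RU) and phase labels.

    Phase labels must be contiguous, the association block preceding the
    dissociation block; times strictly increasing; at least two points
    per phase present in observed data.
    """

    analyte_conc: float
    time: np.ndarray
    response: np.ndarray
    phase: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (self.time.shape == self.response.shape == self.phase.shape):
            raise SensorgramFormatError("time/response/phase length mismatch")
        if self.time.size < 2:
            raise SensorgramFormatError("cycle needs at least 2 points")
        bad = set(np.unique(self.phase)) - {ASSOC, DISSOC}
        if bad:
            raise SensorgramFormatError(f"unknown phase label(s) {bad}")
        is_d = self.phase == DISSOC
        if np.any(np.diff(is_d.astype(int)) < 0):
            raise SensorgramFormatError(
                "phase blocks must be contiguous with association first")

    @property
    def n_points(self) -> int:
        return int(self.time.size)

    @property
    def assoc_mask(self) -> np.ndarray:
        return self.phase == ASSOC

    @property
    def dissoc_mask(self) -> np.ndarray:
        return self.phase == DISSOC


@dataclass
class TitrationSeries:
    """A titration sensorgram: one :class:`CyclePhases` per analyte
    concentration, in injection order."""

    cycles: list[CyclePhases]

    def __post_init__(self):
        if not self.cycles:
            raise SensorgramFormatError("TitrationSeries needs >=1 cycle")
        for j, c in enumerate(self.cycles, start=1):
            if np.any(np.diff(c.time) <= 0):
                raise SensorgramFormatError(
                    f"cycle {j}: time not strictly increasing")

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def n_points(self) -> int:
        return sum(c.n_points for c in self.cycles)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c.analyte_conc for c in self.cycles])

    def responses(self) -> np.ndarray:
        """All observed responses, cycles concatenated in order."""
        return np.concatenate([c.response for c in self.cycles])

    def select(self, concentrations: Sequence[float],
               rtol: float = 1e-6) -> "TitrationSeries":
        """Sub-series restricted to the given concentrations (in the
        given order); used to pick the fitted linear-range cycles."""
        chosen = []
        for target in concentrations:
            match = [c for c in self.cycles
                     if np.isclose(c.analyte_conc, target, rtol=rtol)]
            if not match:
                raise KeyError(f"no cycle at concentration {target!r} M")
            chosen.append(match[0])
        return TitrationSeries(cycles=chosen)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for j, c in enumerate(self.cycles, start=1):
            frames.append(pd.DataFrame({
                "cycle": j,
                "concentration_M": c.analyte_conc,
                "time_s": c.time,
                "response_RU": c.response,
                "phase": c.phase,
            }))
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TitrationSeries":
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise SensorgramFormatError(
                f"missing column(s): {', '.join(missing)}")
        df = df.sort_values(["cycle", "time_s"], kind="stable")
        cycles = []
        for _, grp in df.groupby("cycle", sort=True):
            conc = grp["concentration_M"].to_numpy(dtype=float)
            if conc.size and np.ptp(conc) > 0:
                raise SensorgramFormatError(
                    "concentration_M must be constant within a cycle")
            cycles.append(CyclePhases(
                analyte_conc=float(conc[0]),
                time=grp["time_s"].to_numpy(dtype=float),
                response=grp["response_RU"].to_numpy(dtype=float),
                phase=grp["phase"].to_numpy(dtype=object),
            ))
        return cls(cycles=cycles)


def read_sensorgram_csv(path) -> TitrationSeries:
    """Read a long-format sensorgram CSV; rows are sorted by cycle then
    time, so shuffled files load identically to sorted ones."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    return TitrationSeries.from_frame(df)


def write_sensorgram_csv(series: TitrationSeries, path) -> None:
    """Write the canonical long-format CSV at full float precision
    (Python repr, shortest round-trip representation)."""
    df = series.to_frame()
    df.to_csv(path, index=False)


def dose_response_summary(series: TitrationSeries,
                          tail_window: float = 10.0) -> pd.DataFrame:
    """Mean response over the final ``tail_window`` seconds of each
    cycle's association phase, paired with the analyte concentration.

    This is the dose-response curve an operator inspects to pick the
    concentrations in the linear range for the global fit (typically
    the top M=5 of a doubling ladder); it is advisory — the selection
    itself is configured, not automated.
    """
    rows = []
    for j, c in enumerate(series.cycles, start=1):
        t = c.time[c.assoc_mask]
        r = c.response[c.assoc_mask]
        if t.size < 2:
            raise SensorgramFormatError(f"cycle {j}: no association phase")
        span = t[-1] - t[0]
        if tail_window >= span:
            raise ValueError(
                f"tail_window {tail_window} s >= association span {span} s "
                f"in cycle {j}")
        sel = t >= t[-1] - tail_window
        rows.append({
            "cycle": j,
            "concentration_M": c.analyte_conc,
            "end_of_association_RU": float(np.mean(r[sel])),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run configuration

#: default grid-search axes: three decade-spaced initial values per
#: kinetic parameter (3^4 = 81 starts)
DEFAULT_GRID = {
    "ka1": [1e2, 1e3, 1e4],
    "kd1": [1e-4, 1e-3, 1e-2],
    "ka2": [1e-5, 1e-4, 1e-3],
    "kd2": [1e-5, 1e-4, 1e-3],
}


@dataclass
class FitConfig:
    """Run configuration for fitting and profiling.

    concentrations : molar values to fit (None = all cycles in the file)
    grid : per-parameter lists of initial values for the grid search
    sigma : measurement-error SD in RU, or "estimate" to use the
        residual SD of the best fit
    regenerative : drop the per-cycle t* parameters (surface stripped
        between cycles)
    tstar_init : initial t* for non-regenerative fits, s
    profile_points / profile_decades_below / profile_decades_above :
        profile-likelihood grid (log-spaced)
    profile_floor : lower anchor when a parameter is estimated at the
        zero bound, in the parameter's units
    profile_ftol / profile_max_nfev : convergence controls for the
        constrained (clamped) re-fits; looser than the main fit since
        the profile only needs NLL resolution well below the
        chi-square threshold step
    alpha : confidence level for the identifiability threshold
    df : degrees of freedom for the chi-square threshold ("np" = number
        of fitted parameters, the joint threshold; or 1 per-parameter)
    ftol / gtol / max_nfev : least-squares convergence controls
    grid_max_nfev : iteration cap for the per-start exploratory fits of
        the grid search; the winning start is then re-polished under
        the full ``max_nfev`` budget
    rtol / atol : ODE integrator tolerances
    """

    concentrations: list[float] | None = None
    grid: dict[str, list[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_GRID.items()})
    sigma: float | str = "estimate"
    regenerative: bool = False
    tstar_init: float = 60.0
    rmax_init_factor: float = 2.0
    profile_points: int = 21
    profile_decades_below: float = 3.0
    profile_decades_above: float = 2.0
    profile_floor: float = 1e-8
    profile_ftol: float = 1e-8
    profile_max_nfev: int = 300
    alpha: float = 0.95
    df: int | str = "np"
    ftol: float = 1e-10
    gtol: float = 1e-10
    max_nfev: int = 1000
    grid_max_nfev: int = 150
    rtol: float = 1e-8
    atol: float = 1e-10
    seed: int = 0
    workers: int = 1

    def __post_init__(self):
        for name in ("ka1", "kd1", "ka2", "kd2"):
            axis = self.grid.get(name)
            if not axis:
                raise ValueError(f"grid axis {name!r} must be non-empty")
        if isinstance(self.sigma, str):
            if self.sigma != "estimate":
                raise ValueError("sigma must be a positive number or 'estimate'")
        elif self.sigma <= 0:
            raise ValueError("numeric sigma must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.df != "np" and self.df != 1:
            raise ValueError("df must be 1 or 'np'")
        if self.profile_points < 5:
            raise ValueError("profile grid needs >= 5 points")

    @classmethod
    def from_yaml(cls, path) -> "FitConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
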