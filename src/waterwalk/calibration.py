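"""Chi-squared calibration of simulated trip times against observed travel times.

The simulated trip-time distribution for a candidate parameter pair
(alpha, borehole threshold) is binned and compared with the observed
(questionnaire-style) distribution by a goodness-of-fit statistic
sum (O - E)^2 / E, where O are simulated bin counts and E the observed bin
proportions scaled to the simulated sample size.  A sweep over the
(alpha x threshold) plane, with repeats, reproduces the calibration matrix;
the minimum-mean-statistic cell is the fitted parameter pair, and any cell
below the 95% chi-squared critical value (9.488 at df = 4) is statistically
indistinguishable from the observations.

A single-agent-per-village rerun in deterministic-expectation mode yields
per-village signed errors (simulated minus observed minutes), whose square
roots map the spatial error pattern.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path as FsPath
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import LandscapeGrid, SiteSet
from .movement import (
    SimulationParams,
    TripRecord,
    WaterChoiceParams,
    build_path_library,
    run_population,
    simulate_trips_batch,
    village_water_menu,
)
from .pathfinding import Path, SearchParams, path_metrics

__all__ = [
    "ObservedTimes",
    "BinSpec",
    "ChiSqResult",
    "SweepResult",
    "ErrorRecord",
    "bin_times",
    "chi_squared_gof",
    "sweep_parameters",
    "individual_errors",
    "summarize_errors",
    "export_error_map",
    "generate_observed_times",
    "parameter_recovery",
    "DegenerateDistributionError",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS_KM = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0)
DEFAULT_ALPHAS = (0.0, 5.0, 15.0, 25.0, 35.0, 45.0)


class DegenerateDistributionError(ValueError):
    """The observed distribution collapses into a single bin; no test possible."""


@dataclass
class ObservedTimes:
    """Reported one-way travel times to water, in minutes, tagged by village."""

    records: list[tuple[str, float]]

    def __post_init__(self):
        if not self.records:
            raise ValueError("observed sample must be non-empty")
        if any(m <= 0 for _, m in self.records):
            raise ValueError("observed minutes must be positive")

    @property
    def minutes(self) -> np.ndarray:
        return np.array([m for _, m in self.records], dtype=float)

    @classmethod
    def from_csv(cls, file) -> "ObservedTimes":
        df = pd.read_csv(file)
        return cls([(str(r.village_id), float(r.minutes)) for r in df.itertuples(index=False)])

    def to_csv(self, file) -> None:
        pd.DataFrame(self.records, columns=["village_id", "minutes"]).to_csv(file, index=False)


@dataclass(frozen=True)
class BinSpec:
    """Strictly increasing minute boundaries defining k = len(edges) - 1 bins.

    Bins are half-open [lo, hi); the last bin is open-ended above its lower
    edge, and values below the first edge fall into the first bin.
    """

    edges: tuple[float, ...]

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=float)
        if len(e) < 3:
            raise ValueError("need at least 3 edges (2 bins)")
        if not np.all(np.diff(e) > 0):
            raise ValueError("edges must be strictly increasing")

    @property
    def k(self) -> int:
        return len(self.edges) - 1

    @classmethod
    def quantile(cls, times: Sequence[float], k: int = 5) -> "BinSpec":
        """Equal-expected-count bins at quantiles of a reference sample.

        Inner edges are snapped to the midpoint between adjacent distinct
        sample values, so that for discrete time distributions (trip times
        are whole iterations) no support point sits exactly on a boundary.
        Duplicate edges are dropped, which can reduce the bin count below
        ``k``.
        """
        t = np.asarray(times, dtype=float)
        vals = np.unique(t)
        qs = np.linspace(0.0, 1.0, k + 1)
        raw = np.quantile(t, qs)
        edges = [raw[0]]
        for q in raw[1:-1]:
            j = int(np.searchsorted(vals, q, side="left"))
            if 0 < j < len(vals):
                edges.append(0.5 * (vals[j - 1] + vals[j]))
            else:
                edges.append(q)
        edges.append(raw[-1])
        edges = np.unique(edges)
        if len(edges) < 3:
            raise DegenerateDistributionError("sample too concentrated for >= 2 bins")
        return cls(tuple(edges))


def bin_times(times: Sequence[float], spec: BinSpec) -> np.ndarray:
    """Histogram counts under the spec's boundary convention; sums to len(times)."""
    t = np.asarray(times, dtype=float)
    idx = np.searchsorted(np.asarray(spec.edges), t, side="right") - 1
    idx = np.clip(idx, 0, spec.k - 1)
    return np.bincount(idx, minlength=spec.k)


@dataclass(frozen=True)
class ChiSqResult:
    statistic: float
    df: int
    critical_value: float
    significant: bool


def chi_squared_gof(
    sim_times: Sequence[float],
    observed: ObservedTimes,
    spec: BinSpec,
) -> ChiSqResult:
    """Goodness of fit of simulated trip times to the observed distribution.

    Expected counts are the observed bin proportions scaled to the simulated
    sample size; bins whose expected count falls below 5 are merged from the
    top (long-trip tail) downwards.  ``significant`` means the simulated
    distribution deviates from the observed one at the 95% level.
    """
    sim = np.asarray(sim_times, dtype=float)
    if sim.size == 0:
        raise ValueError("simulated sample must be non-empty")
    O = bin_times(sim, spec).astype(float)
    obs_counts = bin_times(observed.minutes, spec).astype(float)
    props = obs_counts / obs_counts.sum()
    E = props * sim.size
    while len(E) > 2 and (E.min() < 5.0):
        O[-2] += O[-1]
        E[-2] += E[-1]
        O, E = O[:-1], E[:-1]
    if len(E) < 2 or np.count_nonzero(E) < 2:
        raise DegenerateDistributionError("observed distribution collapses to one bin")
    if E.min() <= 0:
        # an empty expected bin that survived merging makes the statistic undefined
        raise DegenerateDistributionError("expected count of zero after merging")
    statistic = float(((O - E) ** 2 / E).sum())
    df = len(E) - 1
    critical = float(stats.chi2.ppf(0.95, df))
    return ChiSqResult(statistic, df, critical, statistic >= critical)


@dataclass
class SweepResult:
    """Mean and spread of the goodness-of-fit statistic over the parameter plane.

    Rows follow ``alphas`` (labelled H10G00 ... H10G45), columns
    ``thresholds_km``; the machine analogue of the calibration matrix.
    """

    alphas: tuple[float, ...]
    thresholds_km: tuple[float, ...]
    mean: np.ndarray
    sd: np.ndarray
    n_repeats: int
    critical_value: float

    @property
    def labels(self) -> list[str]:
        return [f"H10G{int(a):02d}" for a in self.alphas]

    def best_cells(self) -> list[tuple[float, float]]:
        """Parameter pair(s) with the minimum mean statistic."""
        m = np.nanmin(self.mean)
        out = []
        for i, a in enumerate(self.alphas):
            for j, t in enumerate(self.thresholds_km):
                if self.mean[i, j] == m:
                    out.append((a, t))
        return out

    def nonsignificant_cells(self) -> list[tuple[float, float]]:
        """Cells whose mean statistic sits below the 95% critical value."""
        return [
            (a, t)
            for i, a in enumerate(self.alphas)
            for j, t in enumerate(self.thresholds_km)
            if self.mean[i, j] < self.critical_value
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mean, index=self.labels, columns=list(self.thresholds_km))

    def to_csv(self, file) -> None:
        df = self.to_frame()
        df.index.name = "A* input"
        df.to_csv(file)


def _derive_seeds(seed: int, n: int) -> np.ndarray:
    """n deterministic child seeds below 2**31."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) & 0x7FFFFFFF


def sweep_parameters(
    grid: LandscapeGrid,
    sites: SiteSet,
    observed: ObservedTimes,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    thresholds_km: Sequence[float] = DEFAULT_THRESHOLDS_KM,
    n_repeats: int = 100,
    seed: int = 0,
    *,
    search: SearchParams | None = None,
    choice: WaterChoiceParams | None = None,
    sim: SimulationParams | None = None,
    bin_spec: BinSpec | None = None,
    path_libraries: Mapping[float, Mapping] | None = None,
) -> SweepResult:
    """Run the (alpha x borehole threshold) calibration sweep.

    Each cell runs the population ``n_repeats`` times with distinct derived
    seeds and records the mean and sd of the goodness-of-fit statistic
    against ``observed``.  Routes default to the heuristic-accumulating
    ("as printed") search mode, under which the route family varies
    continuously with alpha.
    """
    search = search or SearchParams(g_mode="as_printed")
    choice = choice or WaterChoiceParams()
    sim = sim or SimulationParams()
    bin_spec = bin_spec or BinSpec.quantile(observed.minutes, 5)
    if path_libraries is None:
        path_libraries = build_path_library(grid, sites, alphas, search, choice)

    n_a, n_t = len(alphas), len(thresholds_km)
    # common random numbers: every sweep cell reuses the same per-repeat seeds,
    # so cell-to-cell differences in the mean statistic reflect the parameters,
    # not independent sampling noise
    seeds = _derive_seeds(seed, n_repeats * 2).reshape(n_repeats, 2)
    mean = np.empty((n_a, n_t))
    sd = np.empty((n_a, n_t))
    crit = math.nan
    for i, a in enumerate(alphas):
        paths = path_libraries[a]
        for j, thr in enumerate(thresholds_km):
            statistics = []
            for r in range(n_repeats):
                ch = replace(choice, borehole_threshold_km=thr, seed=int(seeds[r, 0]))
                sm = replace(sim, seed=int(seeds[r, 1]))
                records = run_population(grid, sites, paths, sim.n_agents, ch, sm, alpha=a)
                res = chi_squared_gof([t.trip_minutes for t in records], observed, bin_spec)
                statistics.append(res.statistic)
                crit = res.critical_value
            mean[i, j] = float(np.mean(statistics))
            sd[i, j] = float(np.std(statistics, ddof=1)) if n_repeats > 1 else 0.0
    return SweepResult(tuple(alphas), tuple(thresholds_km), mean, sd, n_repeats, crit)


# ---------------------------------------------------------------------------
# Per-village error analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorRecord:
    """Signed simulation error for one village (simulated minus observed minutes)."""

    village_id: str
    sim_minutes: float
    obs_minutes: float
    error: float
    sqrt_abs_error: float
    row: int
    col: int


def individual_errors(
    grid: LandscapeGrid,
    sites: SiteSet,
    observed_by_village: Mapping[str, float],
    *,
    search: SearchParams | None = None,
    choice: WaterChoiceParams | None = None,
    speed_table=None,
    seed: int = 0,
    stochastic: bool = False,
    sim: SimulationParams | None = None,
) -> list[ErrorRecord]:
    """One agent per village: simulated-vs-observed walk-time errors.

    By default the simulated time is the deterministic expectation
    (sum step_length / speed) so errors are reproducible; ``stochastic=True``
    walks the path through the iteration clock instead.  Villages without an
    observed time are skipped with a warning.
    """
    from .landscape import SpeedTable

    search = search or SearchParams(alpha=25.0, g_mode="as_printed")
    choice = choice or WaterChoiceParams()
    speed_table = speed_table or SpeedTable()
    sim = sim or SimulationParams(speed_table=speed_table, seed=seed)
    rng = np.random.default_rng(seed)
    menus = village_water_menu(grid, sites, choice)
    from .pathfinding import astar_path

    out: list[ErrorRecord] = []
    for v in sites.villages:
        if v.id not in observed_by_village:
            logger.warning("village %s has no observed time; skipped", v.id)
            continue
        menu = menus[v.id]
        if menu.nearest_borehole_km <= choice.borehole_threshold_km:
            goal = menu.nearest_borehole
        else:
            goal = menu.riverine[int(rng.integers(len(menu.riverine)))]
        path = astar_path(grid, (v.row, v.col), goal, search)
        if stochastic:
            n_iter = int(simulate_trips_batch(path, 1, sim, rng)[0])
            sim_min = n_iter * sim.iteration_s / 60.0
        else:
            sim_min = path_metrics(path, grid, speed_table).ideal_time_min
        obs = float(observed_by_village[v.id])
        err = sim_min - obs
        out.append(
            ErrorRecord(v.id, sim_min, obs, err, math.sqrt(abs(err)), v.row, v.col)
        )
    return out


def summarize_errors(errors: Sequence[ErrorRecord], within_minutes: float = 14.0) -> dict:
    """Mean/max absolute error and the fraction of villages within a tolerance."""
    if not errors:
        return {"mean_abs_error": math.nan, "max_abs_error": math.nan, "frac_within": math.nan}
    abs_err = np.array([abs(e.error) for e in errors])
    return {
        "mean_abs_error": float(abs_err.mean()),
        "max_abs_error": float(abs_err.max()),
        "frac_within": float((abs_err <= within_minutes).mean()),
    }


def export_error_map(errors: Sequence[ErrorRecord], path) -> None:
    """CSV of per-village errors for spatial plotting; header-only when empty."""
    pd.DataFrame(
        [
            {
                "village_id": e.village_id,
                "row": e.row,
                "col": e.col,
                "error_min": e.error,
                "sqrt_abs_error": e.sqrt_abs_error,
            }
            for e in errors
        ],
        columns=["village_id", "row", "col", "error_min", "sqrt_abs_error"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Synthetic observed data and parameter recovery
# ---------------------------------------------------------------------------

def generate_observed_times(
    grid: LandscapeGrid,
    sites: SiteSet,
    *,
    alpha: float = 25.0,
    threshold_km: float = 1.0,
    n_agents: int = 1500,
    seed: int = 0,
    search: SearchParams | None = None,
    choice: WaterChoiceParams | None = None,
    sim: SimulationParams | None = None,
    paths: Mapping | None = None,
) -> ObservedTimes:
    """Synthetic stand-in for questionnaire travel times: trips simulated at a
    known (alpha, threshold), one reported time per agent."""
    search = search or SearchParams(g_mode="as_printed")
    choice = choice or WaterChoiceParams()
    sim = sim or SimulationParams()
    s1, s2 = (int(s) for s in _derive_seeds(seed, 2))
    ch = replace(choice, borehole_threshold_km=threshold_km, seed=s1)
    sm = replace(sim, seed=s2)
    if paths is None:
        paths = build_path_library(grid, sites, [alpha], search, ch)[alpha]
    records = run_population(grid, sites, paths, n_agents, ch, sm, alpha=alpha)
    recs = [(t.village_id, t.trip_minutes) for t in records if t.trip_minutes > 0]
    return ObservedTimes(recs)


def parameter_recovery(
    grid: LandscapeGrid,
    sites: SiteSet,
    *,
    true_alpha: float = 25.0,
    true_threshold_km: float = 1.0,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    thresholds_km: Sequence[float] = DEFAULT_THRESHOLDS_KM,
    n_trials: int = 20,
    n_repeats: int = 10,
    n_observed_agents: int = 1500,
    n_agents: int = 2000,
    seed: int = 0,
    search: SearchParams | None = None,
    choice: WaterChoiceParams | None = None,
    sim: SimulationParams | None = None,
) -> tuple[float, list[tuple[float, float]]]:
    """Plant known parameters, sweep, and see how often the minimum-mean cell
    recovers them.

    Returns the recovery rate over ``n_trials`` and the per-trial best cell.
    Route libraries are computed once and shared across trials.
    """
    search = search or SearchParams(g_mode="as_printed")
    choice = choice or WaterChoiceParams()
    base_sim = sim or SimulationParams(n_agents=n_agents)
    all_alphas = sorted(set(alphas) | {true_alpha})
    libraries = build_path_library(grid, sites, all_alphas, search, choice)
    seeds = _derive_seeds(seed, 2 * n_trials).reshape(n_trials, 2)
    best_cells: list[tuple[float, float]] = []
    hits = 0
    for trial in range(n_trials):
        observed = generate_observed_times(
            grid,
            sites,
            alpha=true_alpha,
            threshold_km=true_threshold_km,
            n_agents=n_observed_agents,
            seed=int(seeds[trial, 0]),
            search=search,
            choice=choice,
            sim=base_sim,
            paths=libraries[true_alpha],
        )
        sweep = sweep_parameters(
            grid,
            sites,
            observed,
            alphas=alphas,
            thresholds_km=thresholds_km,
            n_repeats=n_repeats,
            seed=int(seeds[trial, 1]),
            search=search,
            choice=choice,
            sim=replace(base_sim, n_agents=n_agents),
            path_libraries=libraries,
        )
        best = sweep.best_cells()
        best_cells.append(best[0])
        if len(best) == 1 and best[0] == (true_alpha, true_threshold_km):
            hits += 1
    return hits / n_trials, best_cells
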