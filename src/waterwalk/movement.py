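"""Water-source choice and the timed agent walk in 18-second iterations.

Each agent lives in a village, is assigned a water source (the nearest
borehole if one lies within the borehole threshold, otherwise one of the
three riverine sites closest to the village) and walks the precomputed route
in discrete simulation iterations of 18 s (4800 per day).  Within an
iteration the agent takes whole steps while the remaining time budget allows;
a step that only partly fits is taken with probability
remaining_budget / step_time, so the expected distance covered per iteration
equals the deterministic budget.  The final, partly used iteration is counted
with probability (time used)/(iteration length), which keeps the recorded
trip time an unbiased estimate of the deterministic walking time while
remaining a whole number of iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage

from .landscape import LandscapeGrid, SiteSet, Site, SpeedTable, river_adjacent_cells
from .pathfinding import Path, SearchParams, astar_path

__all__ = [
    "WaterChoiceParams",
    "SimulationParams",
    "TripRecord",
    "sample_riverine_sites",
    "assign_water_source",
    "simulate_trip",
    "simulate_trips_batch",
    "run_population",
    "village_water_menu",
    "build_path_library",
    "trip_records_to_csv",
    "NoRiverError",
    "MissingPathError",
]

SECONDS_PER_DAY = 86400.0


class NoRiverError(RuntimeError):
    """The grid contains no river, so riverine watering sites cannot be sampled."""


class MissingPathError(KeyError):
    """A precomputed route required for a (village, source) pair is absent."""


@dataclass(frozen=True)
class WaterChoiceParams:
    """How agents pick their water source.

    borehole_threshold_km: the distance an agent will travel to prefer a
    borehole over nearer riverine water (sweep set {0.5, 1, 2, 3, 4, 5} km).
    n_riverine_candidates: size of the random sample of river-bank cells that
    serve as potential riverine sites (1000).  n_closest: each village draws
    uniformly among this many closest riverine sites (3).
    """

    borehole_threshold_km: float = 1.0
    n_riverine_candidates: int = 1000
    n_closest: int = 3
    seed: int = 0
    #: study-level seed for drawing the riverine candidate sample; kept separate
    #: from ``seed`` so repeat runs re-randomise agents but not the water map
    riverine_sample_seed: int = 0

    def __post_init__(self):
        if self.borehole_threshold_km <= 0:
            raise ValueError("borehole_threshold_km must be > 0")
        if self.n_closest < 1:
            raise ValueError("n_closest must be >= 1")


@dataclass(frozen=True)
class SimulationParams:
    """Clock discretisation and population size of the agent simulation."""

    iteration_s: float = 18.0
    n_agents: int = 5000
    speed_table: SpeedTable = field(default_factory=SpeedTable)
    seed: int = 0

    def __post_init__(self):
        if self.iteration_s <= 0:
            raise ValueError("iteration_s must be > 0")
        if abs(self.iterations_per_day * self.iteration_s - SECONDS_PER_DAY) > 1e-6:
            raise ValueError("iteration_s must divide the 86400 s day exactly")

    @property
    def iterations_per_day(self) -> int:
        return int(round(SECONDS_PER_DAY / self.iteration_s))


@dataclass(frozen=True)
class TripRecord:
    """One agent's simulated one-way journey from village to water source."""

    agent_id: int
    village_id: str
    source_kind: str  # "borehole" | "riverine"
    source_cell: tuple[int, int]
    trip_minutes: float
    n_iterations: int
    alpha: float | None = None
    borehole_threshold_km: float | None = None
    seed: int | None = None


def sample_riverine_sites(
    grid: LandscapeGrid, n: int, seed: int
) -> list[tuple[int, int]]:
    """Sample ``n`` river-bank cells without replacement (all of them if fewer exist)."""
    bank = river_adjacent_cells(grid)
    if not bank:
        raise NoRiverError("grid contains no river cells")
    if len(bank) <= n:
        return bank
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(bank), size=n, replace=False)
    return [bank[i] for i in sorted(idx)]


def _dist_km(a: tuple[int, int], b: tuple[int, int], cell_size_m: float) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1]) * cell_size_m / 1000.0


def assign_water_source(
    village: tuple[int, int],
    boreholes: Iterable[tuple[int, int]],
    riverine_sites: list[tuple[int, int]],
    params: WaterChoiceParams,
    rng: np.random.Generator,
    cell_size_m: float = 11.0,
) -> tuple[str, tuple[int, int]]:
    """Pick a water source for one agent of a village.

    The nearest borehole within the threshold (straight-line distance) wins
    deterministically; otherwise one of the ``n_closest`` riverine sites is
    chosen uniformly at random.  Returns ``(kind, cell)``.
    """
    best = None
    for bh in boreholes:
        d = _dist_km(village, bh, cell_size_m)
        if d <= params.borehole_threshold_km:
            key = (d, bh)
            if best is None or key < best:
                best = key
    if best is not None:
        return "borehole", best[1]
    if not riverine_sites:
        raise ValueError("no riverine sites available")
    ranked = sorted(riverine_sites, key=lambda rc: (_dist_km(village, rc, cell_size_m), rc))
    top = ranked[: params.n_closest]
    return "riverine", top[int(rng.integers(len(top)))]


# ---------------------------------------------------------------------------
# Trip simulation
# ---------------------------------------------------------------------------

class _StepSchedule:
    """Per-path iteration table: from step-pointer i, one 18 s iteration
    advances to j(i) full steps with probability 1-p(i), or j(i)+1 with p(i)."""

    def __init__(self, path: Path, speed_table: SpeedTable, iteration_s: float):
        speeds = speed_table.as_m_per_s()
        t = path.step_lengths_m / speeds[path.classes[1:]] if len(path.cells) > 1 else np.empty(0)
        self.t = t
        self.n = len(t)
        self.S = np.concatenate([[0.0], np.cumsum(t)])
        self.B = iteration_s
        self.total_s = float(self.S[-1])
        if self.n:
            targets = self.S[:-1] + iteration_s
            j = np.searchsorted(self.S, targets + 1e-9, side="right") - 1
            j = np.minimum(j, self.n)
            r = targets - self.S[j]
            p = np.zeros(self.n)
            inner = j < self.n
            p[inner] = np.clip(r[inner] / t[j[inner]], 0.0, 1.0)
            self.j = j
            self.p = p
        else:
            self.j = np.empty(0, dtype=int)
            self.p = np.empty(0)

    def simulate(self, n_trips: int, rng: np.random.Generator) -> np.ndarray:
        """Iteration counts for ``n_trips`` independent walks of the path."""
        iters = np.zeros(n_trips, dtype=np.int64)
        if self.n == 0:
            return iters
        pos = np.zeros(n_trips, dtype=np.int64)
        active = np.arange(n_trips)
        while active.size:
            cur = pos[active]
            j = self.j[cur]
            take = rng.random(active.size) < self.p[cur]
            new = np.where(take, j + 1, j)
            new = np.minimum(new, self.n)
            iters[active] += 1
            reached = new >= self.n
            if reached.any():
                done = active[reached]
                # final iteration counted in proportion to the ideal time it consumed
                used = (self.total_s - self.S[pos[done]]) / self.B
                drop = rng.random(done.size) >= np.clip(used, 0.0, 1.0)
                iters[done[drop]] -= 1
            pos[active] = new
            active = active[~reached]
        return iters


def simulate_trips_batch(
    path: Path,
    n_trips: int,
    sim: SimulationParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate many walks of one path at once; returns iteration counts."""
    return _StepSchedule(path, sim.speed_table, sim.iteration_s).simulate(n_trips, rng)


def simulate_trip(
    path: Path,
    sim: SimulationParams,
    rng: np.random.Generator,
    *,
    agent_id: int = 0,
    village_id: str = "",
    source_kind: str = "riverine",
    alpha: float | None = None,
    borehole_threshold_km: float | None = None,
    seed: int | None = None,
) -> TripRecord:
    """Walk one path once; a single-cell path takes zero iterations."""
    n_iter = int(simulate_trips_batch(path, 1, sim, rng)[0])
    return TripRecord(
        agent_id=agent_id,
        village_id=village_id,
        source_kind=source_kind,
        source_cell=path.cells[-1],
        trip_minutes=n_iter * sim.iteration_s / 60.0,
        n_iterations=n_iter,
        alpha=alpha,
        borehole_threshold_km=borehole_threshold_km,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Population runs
# ---------------------------------------------------------------------------

@dataclass
class VillageMenu:
    """Per-village water options: the nearest reachable borehole (with its
    straight-line distance) and the n closest reachable riverine sites."""

    village: Site
    nearest_borehole: tuple[int, int] | None
    nearest_borehole_km: float
    riverine: list[tuple[int, int]]


_MENU_CACHE: dict[tuple, dict[str, "VillageMenu"]] = {}


def village_water_menu(
    grid: LandscapeGrid,
    sites: SiteSet,
    choice: WaterChoiceParams,
) -> dict[str, VillageMenu]:
    """Candidate water sources per village.

    River-bank candidates are first down-sampled to ``n_riverine_candidates``
    (seeded), then restricted — like the boreholes — to the village's
    8-connected passable component: water across an impassable river cannot
    be fetched.  The result depends only on the landscape and the sampling
    parameters (not on the threshold), so it is memoised.
    """
    key = (
        id(grid), id(sites),
        choice.n_riverine_candidates, choice.riverine_sample_seed, choice.n_closest,
    )
    cached = _MENU_CACHE.get(key)
    if cached is not None:
        return cached
    labels, _ = ndimage.label(grid.passable_mask(), structure=np.ones((3, 3), int))
    riverine = sample_riverine_sites(grid, choice.n_riverine_candidates, choice.riverine_sample_seed)
    menus: dict[str, VillageMenu] = {}
    for v in sites.villages:
        comp = labels[v.row, v.col]
        vcell = (v.row, v.col)
        best = None
        for bh in sites.boreholes:
            if labels[bh.row, bh.col] != comp:
                continue
            d = _dist_km(vcell, (bh.row, bh.col), grid.cell_size_m)
            if best is None or (d, (bh.row, bh.col)) < best:
                best = (d, (bh.row, bh.col))
        reachable = [rc for rc in riverine if labels[rc] == comp]
        ranked = sorted(reachable, key=lambda rc: (_dist_km(vcell, rc, grid.cell_size_m), rc))
        menus[v.id] = VillageMenu(
            village=v,
            nearest_borehole=None if best is None else best[1],
            nearest_borehole_km=math.inf if best is None else best[0],
            riverine=ranked[: choice.n_closest],
        )
    if len(_MENU_CACHE) > 32:
        _MENU_CACHE.clear()
    _MENU_CACHE[key] = menus
    return menus


def build_path_library(
    grid: LandscapeGrid,
    sites: SiteSet,
    alphas: Iterable[float],
    search_base: SearchParams,
    choice: WaterChoiceParams,
) -> dict[float, dict[tuple[str, tuple[int, int]], Path]]:
    """Precompute A* routes from every village to every water option, per alpha."""
    menus = village_water_menu(grid, sites, choice)
    library: dict[float, dict[tuple[str, tuple[int, int]], Path]] = {}
    for alpha in alphas:
        params = replace(search_base, alpha=alpha)
        paths: dict[tuple[str, tuple[int, int]], Path] = {}
        for vid, menu in menus.items():
            start = (menu.village.row, menu.village.col)
            targets = list(menu.riverine)
            if menu.nearest_borehole is not None:
                targets.append(menu.nearest_borehole)
            for goal in targets:
                paths[(vid, goal)] = astar_path(grid, start, goal, params)
        library[alpha] = paths
    return library


def run_population(
    grid: LandscapeGrid,
    sites: SiteSet,
    paths_by_od: Mapping[tuple[str, tuple[int, int]], Path],
    n_agents: int,
    choice: WaterChoiceParams,
    sim: SimulationParams,
    *,
    alpha: float | None = None,
) -> list[TripRecord]:
    """Place agents uniformly at random across villages, assign each a water
    source, and simulate every one-way trip once.

    Requires a precomputed route for every (village, chosen source) pair;
    a missing route raises :class:`MissingPathError`.
    """
    if not sites.villages:
        raise ValueError("at least one village is required")
    rng_choice = np.random.default_rng(choice.seed)
    rng_sim = np.random.default_rng(sim.seed)
    menus = village_water_menu(grid, sites, choice)
    vids = [v.id for v in sites.villages]

    village_of = rng_choice.integers(len(vids), size=n_agents)
    # per-village source menus are deterministic given the threshold, so the
    # per-agent draw is only the riverine pick among the village's options
    uses_borehole = np.array(
        [menus[v].nearest_borehole_km <= choice.borehole_threshold_km for v in vids]
    )
    riverine_pick = rng_choice.integers(choice.n_closest, size=n_agents)
    kind: list[str] = []
    source: list[tuple[int, int]] = []
    for a in range(n_agents):
        menu = menus[vids[village_of[a]]]
        if uses_borehole[village_of[a]]:
            kind.append("borehole")
            source.append(menu.nearest_borehole)
        else:
            if not menu.riverine:
                raise ValueError(f"village {menu.village.id} has no reachable riverine site")
            kind.append("riverine")
            source.append(menu.riverine[riverine_pick[a] % len(menu.riverine)])

    # batch-simulate agents sharing the same route, then emit records in agent order
    groups: dict[tuple[str, tuple[int, int]], list[int]] = {}
    for a in range(n_agents):
        groups.setdefault((vids[village_of[a]], source[a]), []).append(a)
    n_iter = np.zeros(n_agents, dtype=np.int64)
    for key in sorted(groups):
        if key not in paths_by_od:
            raise MissingPathError(f"no precomputed path for {key}")
        agents = groups[key]
        n_iter[agents] = simulate_trips_batch(paths_by_od[key], len(agents), sim, rng_sim)

    return [
        TripRecord(
            agent_id=a,
            village_id=vids[village_of[a]],
            source_kind=str(kind[a]),
            source_cell=tuple(source[a]),
            trip_minutes=n_iter[a] * sim.iteration_s / 60.0,
            n_iterations=int(n_iter[a]),
            alpha=alpha,
            borehole_threshold_km=choice.borehole_threshold_km,
            seed=sim.seed,
        )
        for a in range(n_agents)
    ]


def trip_records_to_csv(records: list[TripRecord], file) -> None:
    """Write trip records as CSV."""
    import pandas as pd

    columns = [
        "agent_id",
        "village_id",
        "source_kind",
        "source_row",
        "source_col",
        "alpha",
        "threshold_km",
        "n_iterations",
        "trip_minutes",
        "seed",
    ]
    rows = [
        {
            "agent_id": t.agent_id,
            "village_id": t.village_id,
            "source_kind": t.source_kind,
            "source_row": t.source_cell[0],
            "source_col": t.source_cell[1],
            "alpha": t.alpha,
            "threshold_km": t.borehole_threshold_km,
            "n_iterations": t.n_iterations,
            "trip_minutes": t.trip_minutes,
            "seed": t.seed,
        }
        for t in records
    ]
    pd.DataFrame(rows, columns=columns).to_csv(file, index=False)
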