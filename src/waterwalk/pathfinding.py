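"""Grid pathfinding: weighted A* over the land-cover cost surface, plus a Dijkstra oracle.

Search scores a frontier cell by f = g + h.  The heuristic h is the Euclidean
cell distance to the goal scaled by ``h_scale`` (10 by default).  The cost of
stepping into a cell of class k is C(k) * alpha * step_factor, where C comes
from the :class:`~waterwalk.landscape.CostTable`, alpha weights terrain cost
against directness, and step_factor is 1 for cardinal moves and sqrt(2) for
diagonal ones.  At alpha = 0 the search degenerates to greedy best-first on h
(the straight-line control); as alpha grows the route converges to the
least-cost corridor.

Two accumulation modes are provided.  ``standard`` is textbook A*,
g(child) = g(parent) + increment.  ``as_printed`` accumulates
g(child) = f(parent) + increment, i.e. the parent's heuristic is folded into
the path cost at every step; this variant trades directness against terrain
cost continuously in alpha and is the one used for the calibration sweep.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass, field
from pathlib import Path as FsPath
from typing import NamedTuple

import numpy as np
import pandas as pd

from .landscape import CostTable, LandClass, LandscapeGrid, SpeedTable

__all__ = [
    "SearchParams",
    "Path",
    "PathMetrics",
    "astar_path",
    "dijkstra_path",
    "path_metrics",
    "UnreachableError",
    "path_to_csv",
    "path_to_geojson",
]

SQRT2 = math.sqrt(2.0)

_NEIGHBOURS = tuple(
    (dr, dc, 1.0 if dr == 0 or dc == 0 else SQRT2)
    for dr in (-1, 0, 1)
    for dc in (-1, 0, 1)
    if not (dr == 0 and dc == 0)
)


class UnreachableError(RuntimeError):
    """No passable route exists between start and goal (the river partitions them)."""


@dataclass(frozen=True)
class SearchParams:
    """Weighted-A* knobs.

    alpha >= 0 weights terrain cost against directness; h_scale scales the
    Euclidean heuristic (10 removes the decimal from diagonal moves);
    diagonal_step_factor multiplies the move cost of diagonal steps (sqrt(2)
    exact by default, 1.4 reproduces integer 10/14 rounding).
    """

    alpha: float = 25.0
    h_scale: float = 10.0
    cost_table: CostTable = field(default_factory=CostTable)
    g_mode: str = "standard"
    diagonal_step_factor: float = SQRT2

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.h_scale <= 0:
            raise ValueError("h_scale must be > 0")
        if self.g_mode not in ("standard", "as_printed"):
            raise ValueError("g_mode must be 'standard' or 'as_printed'")


@dataclass
class Path:
    """An ordered, duplicate-free sequence of 8-adjacent passable cells.

    ``terrain_cost`` is the step-factor-weighted sum of C over entered cells
    (cells[1:]), unweighted by alpha; ``length_m`` the metric path length.
    """

    cells: list[tuple[int, int]]
    step_lengths_m: np.ndarray
    classes: np.ndarray
    terrain_cost: float
    length_m: float

    @classmethod
    def from_cells(
        cls,
        grid: LandscapeGrid,
        cells: list[tuple[int, int]],
        cost_table: CostTable,
        diagonal_step_factor: float = SQRT2,
    ) -> "Path":
        codes = np.array([grid.classes[r, c] for r, c in cells], dtype=np.int8)
        costs = cost_table.as_array()
        steps = []
        terrain = 0.0
        for (r0, c0), (r1, c1) in zip(cells[:-1], cells[1:]):
            diag = r0 != r1 and c0 != c1
            steps.append(grid.cell_size_m * (SQRT2 if diag else 1.0))
            terrain += costs[grid.classes[r1, c1]] * (diagonal_step_factor if diag else 1.0)
        lengths = np.asarray(steps)
        return cls(
            cells=list(cells),
            step_lengths_m=lengths,
            classes=codes,
            terrain_cost=float(terrain),
            length_m=float(lengths.sum()) if len(steps) else 0.0,
        )


def _check_endpoints(grid: LandscapeGrid, start, goal) -> None:
    for name, (r, c) in (("start", start), ("goal", goal)):
        if not grid.is_inside(r, c):
            raise ValueError(f"{name} cell ({r}, {c}) is outside the grid")
        if grid.classes[r, c] == LandClass.RIVER:
            raise ValueError(f"{name} cell ({r}, {c}) is on the impassable river")


def _reconstruct_array(parent: np.ndarray, start, goal, n_cols: int) -> list[tuple[int, int]]:
    cells = [goal]
    while cells[-1] != start:
        p = int(parent[cells[-1]])
        cells.append((p // n_cols, p % n_cols))
    cells.reverse()
    return cells


def astar_path(
    grid: LandscapeGrid,
    start: tuple[int, int],
    goal: tuple[int, int],
    params: SearchParams,
) -> Path:
    """Weighted A* route from start to goal.

    Deterministic: ties on f are broken by lower h, then row-major cell order.
    Cells are never re-expanded (single-pass closed set), which matches the
    optimal behaviour whenever the heuristic is admissible (alpha >= 1 with
    the default cost table) and yields a fixed, reproducible route otherwise.

    Raises :class:`UnreachableError` if the river partitions start from goal.
    """
    _check_endpoints(grid, start, goal)
    if start == goal:
        return Path.from_cells(grid, [start], params.cost_table, params.diagonal_step_factor)

    n_rows, n_cols = grid.shape
    gr, gc = goal
    rr = np.arange(n_rows)[:, None]
    cc = np.arange(n_cols)[None, :]
    h_grid = params.h_scale * np.hypot(rr - gr, cc - gc)
    # per-cell move cost for a cardinal step; inf marks the river (kept
    # infinite even at alpha = 0, where passable moves cost nothing)
    base_cost = params.cost_table.as_array()[grid.classes]
    finite = np.isfinite(base_cost)
    step_grid = np.full_like(base_cost, np.inf)
    step_grid[finite] = base_cost[finite] * params.alpha
    diag_mult = params.diagonal_step_factor

    g_best = np.full((n_rows, n_cols), np.inf)
    parent = np.full((n_rows, n_cols), -1, dtype=np.int64)
    closed = np.zeros((n_rows, n_cols), dtype=bool)
    g_best[start] = 0.0
    h0 = float(h_grid[start])
    heap: list[tuple[float, float, int, int]] = [(h0, h0, start[0], start[1])]
    as_printed = params.g_mode == "as_printed"

    while heap:
        f_cur, h_cur, r, c = heapq.heappop(heap)
        if closed[r, c]:
            continue
        if r == gr and c == gc:
            return Path.from_cells(
                grid, _reconstruct_array(parent, start, goal, n_cols),
                params.cost_table, params.diagonal_step_factor,
            )
        closed[r, c] = True
        base = f_cur if as_printed else float(g_best[r, c])
        for dr, dc, sf in _NEIGHBOURS:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < n_rows and 0 <= nc < n_cols) or closed[nr, nc]:
                continue
            cost = step_grid[nr, nc]
            if not math.isfinite(cost):
                continue
            ng = base + (cost if sf == 1.0 else cost * diag_mult)
            if ng < g_best[nr, nc] - 1e-12:
                g_best[nr, nc] = ng
                parent[nr, nc] = r * n_cols + c
                hn = float(h_grid[nr, nc])
                heapq.heappush(heap, (ng + hn, hn, nr, nc))
    raise UnreachableError(f"no passable route from {start} to {goal}")


def dijkstra_path(
    grid: LandscapeGrid,
    start: tuple[int, int],
    goal: tuple[int, int],
    cost_table: CostTable,
    diagonal_step_factor: float = SQRT2,
) -> Path:
    """Exact least-terrain-cost route (step-factor-weighted), used as the A* oracle.

    Tie-breaking mirrors :func:`astar_path`: equal accumulated costs are
    resolved by lower Euclidean distance to goal, then row-major order.
    """
    _check_endpoints(grid, start, goal)
    if start == goal:
        return Path.from_cells(grid, [start], cost_table, diagonal_step_factor)

    n_rows, n_cols = grid.shape
    gr, gc = goal
    rr = np.arange(n_rows)[:, None]
    cc = np.arange(n_cols)[None, :]
    h_grid = np.hypot(rr - gr, cc - gc)
    step_grid = cost_table.as_array()[grid.classes]

    g_best = np.full((n_rows, n_cols), np.inf)
    parent = np.full((n_rows, n_cols), -1, dtype=np.int64)
    closed = np.zeros((n_rows, n_cols), dtype=bool)
    g_best[start] = 0.0
    heap = [(0.0, float(h_grid[start]), start[0], start[1])]

    while heap:
        g_cur, _, r, c = heapq.heappop(heap)
        if closed[r, c]:
            continue
        if r == gr and c == gc:
            return Path.from_cells(
                grid, _reconstruct_array(parent, start, goal, n_cols),
                cost_table, diagonal_step_factor,
            )
        closed[r, c] = True
        for dr, dc, sf in _NEIGHBOURS:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < n_rows and 0 <= nc < n_cols) or closed[nr, nc]:
                continue
            cost = step_grid[nr, nc]
            if not math.isfinite(cost):
                continue
            ng = g_cur + (cost if sf == 1.0 else cost * diagonal_step_factor)
            if ng < g_best[nr, nc] - 1e-12:
                g_best[nr, nc] = ng
                parent[nr, nc] = r * n_cols + c
                heapq.heappush(heap, (ng, float(h_grid[nr, nc]), nr, nc))
    raise UnreachableError(f"no passable route from {start} to {goal}")


class PathMetrics(NamedTuple):
    length_m: float
    terrain_cost: float
    ideal_time_min: float


def path_metrics(path: Path, grid: LandscapeGrid, speed_table: SpeedTable) -> PathMetrics:
    """Length, terrain cost and the deterministic walking time of a path.

    ideal_time_min is the sum of step_length / speed(entered cell), in
    minutes — the expectation against which the stochastic trip simulator is
    unbiased.
    """
    speeds = speed_table.as_m_per_s()
    t_s = 0.0
    for L, code in zip(path.step_lengths_m, path.classes[1:]):
        t_s += L / speeds[code]
    return PathMetrics(float(path.length_m), float(path.terrain_cost), float(t_s) / 60.0)


def path_to_csv(path: Path, file: str | FsPath) -> None:
    """Export a path as ``step,row,col,class,step_length_m`` CSV."""
    rows = []
    for i, (r, c) in enumerate(path.cells):
        rows.append(
            {
                "step": i,
                "row": r,
                "col": c,
                "class": LandClass(int(path.classes[i])).name,
                "step_length_m": 0.0 if i == 0 else float(path.step_lengths_m[i - 1]),
            }
        )
    pd.DataFrame(rows).to_csv(file, index=False)


def path_to_geojson(path: Path, grid: LandscapeGrid, file: str | FsPath) -> None:
    """Export a path as a GeoJSON LineString in grid-metre coordinates."""
    coords = [list(grid.cell_center_xy(r, c)) for r, c in path.cells]
    obj = {
        "type": "Feature",
        "geometry": {"type": "LineString", "coordinates": coords},
        "properties": {
            "length_m": path.length_m,
            "terrain_cost": path.terrain_cost,
            "n_cells": len(path.cells),
        },
    }
    FsPath(file).write_text(json.dumps(obj))
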