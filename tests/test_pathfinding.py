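"""Pathfinding: octile closed forms, oracle equivalences, river avoidance, metrics."""

from __future__ import annotations

import math

import numpy as np
import pytest

from waterwalk.landscape import CostTable, LandClass, LandscapeGrid, SpeedTable
from waterwalk.pathfinding import (
    SQRT2,
    Path,
    SearchParams,
    UnreachableError,
    astar_path,
    dijkstra_path,
    path_metrics,
)

from conftest import octile_length_m, random_terrain_grid, two_corridor_grid, uniform_grid

B, R, C, F, W = (int(c) for c in (LandClass.BARE, LandClass.ROAD, LandClass.CROP,
                                  LandClass.FOREST, LandClass.RIVER))


def brute_force_least_cost(grid: LandscapeGrid, start, goal, cost_table: CostTable) -> float:
    """Exhaustive DFS over all simple paths with branch-and-bound pruning.

    Exact on tiny grids; independent of the heap-based implementations.
    """
    costs = cost_table.as_array()
    best = [math.inf]
    n_rows, n_cols = grid.shape
    visited = {start}

    def visit(cell, acc):
        if acc >= best[0]:
            return
        if cell == goal:
            best[0] = acc
            return
        r, c = cell
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nr, nc = r + dr, c + dc
                if not (0 <= nr < n_rows and 0 <= nc < n_cols):
                    continue
                step_cost = costs[grid.classes[nr, nc]]
                if not math.isfinite(step_cost):
                    continue
                nxt = (nr, nc)
                if nxt in visited:
                    continue
                visited.add(nxt)
                sf = SQRT2 if (dr != 0 and dc != 0) else 1.0
                visit(nxt, acc + step_cost * sf)
                visited.remove(nxt)

    visit(start, 0.0)
    return best[0]


def assert_valid_path(path: Path, grid: LandscapeGrid, start, goal):
    assert path.cells[0] == start and path.cells[-1] == goal
    assert len(set(path.cells)) == len(path.cells)
    for (r0, c0), (r1, c1) in zip(path.cells[:-1], path.cells[1:]):
        assert max(abs(r0 - r1), abs(c0 - c1)) == 1
    for r, c in path.cells:
        assert grid.classes[r, c] != LandClass.RIVER
    assert path.length_m >= math.hypot(
        path.cells[0][0] - goal[0], path.cells[0][1] - goal[1]
    ) * grid.cell_size_m - 1e-9


class TestAstar:
    def test_start_equals_goal(self):
        grid = uniform_grid(5, 5)
        p = astar_path(grid, (2, 2), (2, 2), SearchParams(alpha=5))
        assert p.cells == [(2, 2)]
        assert p.length_m == 0.0
        assert p.terrain_cost == 0.0

    @pytest.mark.parametrize("alpha", [0.0, 1.0, 5.0, 45.0])
    @pytest.mark.parametrize("endpoints", [((0, 0), (19, 19)), ((3, 1), (10, 17)), ((18, 2), (0, 5))])
    def test_uniform_grid_octile_length(self, alpha, endpoints):
        grid = uniform_grid(20, 20)
        start, goal = endpoints
        p = astar_path(grid, start, goal, SearchParams(alpha=alpha))
        assert p.length_m == pytest.approx(octile_length_m(start, goal), rel=1e-9)

    def test_river_wall_gap_is_used(self):
        codes = np.zeros((9, 9), dtype=np.int8)
        codes[:, 4] = W
        codes[6, 4] = B  # the only gap
        grid = LandscapeGrid(codes)
        for alpha in (0.0, 10.0):
            p = astar_path(grid, (1, 1), (1, 7), SearchParams(alpha=alpha))
            assert (6, 4) in p.cells
            assert_valid_path(p, grid, (1, 1), (1, 7))

    def test_two_corridor_least_cost_at_high_alpha(self, two_corridor_grid):
        grid, start, goal = two_corridor_grid
        params = SearchParams(alpha=45.0)
        p = astar_path(grid, start, goal, params)
        d = dijkstra_path(grid, start, goal, params.cost_table)
        assert p.terrain_cost == pytest.approx(d.terrain_cost, rel=1e-12)

    def test_directness_cost_tradeoff_on_fixture(self, two_corridor_grid):
        grid, start, goal = two_corridor_grid
        costs, lengths = [], []
        for alpha in (0.0, 5.0, 15.0, 25.0, 35.0, 45.0):
            p = astar_path(grid, start, goal, SearchParams(alpha=alpha, g_mode="as_printed"))
            costs.append(p.terrain_cost)
            lengths.append(p.length_m)
        assert all(a >= b - 1e-9 for a, b in zip(costs[:-1], costs[1:]))
        assert all(a <= b + 1e-9 for a, b in zip(lengths[:-1], lengths[1:]))

    def test_unreachable_raises(self):
        codes = np.zeros((5, 5), dtype=np.int8)
        codes[:, 2] = W
        grid = LandscapeGrid(codes)
        with pytest.raises(UnreachableError):
            astar_path(grid, (0, 0), (0, 4), SearchParams(alpha=1))

    def test_river_endpoint_rejected(self):
        codes = np.zeros((3, 3), dtype=np.int8)
        codes[1, 1] = W
        grid = LandscapeGrid(codes)
        with pytest.raises(ValueError):
            astar_path(grid, (1, 1), (0, 0), SearchParams(alpha=1))

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        grid = random_terrain_grid(rng, 15, 15, river_prob=0.1)
        p1 = astar_path(grid, (0, 0), (14, 14), SearchParams(alpha=3))
        p2 = astar_path(grid, (0, 0), (14, 14), SearchParams(alpha=3))
        assert p1.cells == p2.cells

    @pytest.mark.parametrize("g_mode", ["standard", "as_printed"])
    @pytest.mark.parametrize("alpha", [0.0, 2.0, 25.0])
    def test_no_river_cell_in_any_path(self, g_mode, alpha):
        rng = np.random.default_rng(99)
        for _ in range(10):
            grid = random_terrain_grid(rng, 12, 16, river_prob=0.15)
            try:
                p = astar_path(grid, (0, 0), (11, 15),
                               SearchParams(alpha=alpha, g_mode=g_mode))
            except UnreachableError:
                continue
            assert_valid_path(p, grid, (0, 0), (11, 15))


class TestDijkstra:
    def test_uniform_grid_closed_form(self):
        grid = uniform_grid(12, 12, land_class=LandClass.CROP)
        ct = CostTable()
        p = dijkstra_path(grid, (0, 0), (7, 11), ct)
        n_diag, n_card = 7, 4
        assert p.terrain_cost == pytest.approx(ct.crop * (n_diag * SQRT2 + n_card), rel=1e-12)

    def test_lower_bound_for_astar(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            grid = random_terrain_grid(rng, 12, 12, river_prob=0.08)
            try:
                d = dijkstra_path(grid, (0, 0), (11, 11), CostTable())
            except UnreachableError:
                continue
            for alpha in (0.0, 0.5, 2.0):
                a = astar_path(grid, (0, 0), (11, 11), SearchParams(alpha=alpha))
                assert d.terrain_cost <= a.terrain_cost + 1e-9

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(21)
        checked = 0
        while checked < 8:
            grid = random_terrain_grid(rng, 5, 5, river_prob=0.12)
            try:
                d = dijkstra_path(grid, (0, 0), (4, 4), CostTable())
            except UnreachableError:
                continue
            expect = brute_force_least_cost(grid, (0, 0), (4, 4), CostTable())
            assert d.terrain_cost == pytest.approx(expect, rel=1e-9)
            checked += 1

    def test_matches_scipy_graph_oracle(self):
        from scipy.sparse import lil_matrix
        from scipy.sparse.csgraph import dijkstra as csgraph_dijkstra

        rng = np.random.default_rng(31)
        grid = random_terrain_grid(rng, 18, 18, river_prob=0.1)
        costs = CostTable().as_array()
        n = 18 * 18
        mat = lil_matrix((n, n))
        for r in range(18):
            for c in range(18):
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == 0 and dc == 0:
                            continue
                        nr, nc = r + dr, c + dc
                        if not (0 <= nr < 18 and 0 <= nc < 18):
                            continue
                        w = costs[grid.classes[nr, nc]]
                        if math.isfinite(w):
                            sf = SQRT2 if dr and dc else 1.0
                            mat[r * 18 + c, nr * 18 + nc] = w * sf
        dist = csgraph_dijkstra(mat.tocsr(), indices=0)
        try:
            d = dijkstra_path(grid, (0, 0), (17, 17), CostTable())
            assert d.terrain_cost == pytest.approx(dist[17 * 18 + 17], rel=1e-9)
        except UnreachableError:
            assert np.isinf(dist[17 * 18 + 17])


class TestOptimalityRegime:
    def test_astar_equals_dijkstra_when_admissible(self):
        rng = np.random.default_rng(77)
        for i in range(20):
            grid = random_terrain_grid(rng, 18, 22, river_prob=0.1)
            alpha = float(rng.choice([1.0, 2.0, 5.0, 45.0]))
            try:
                d = dijkstra_path(grid, (0, 0), (17, 21), CostTable())
            except UnreachableError:
                continue
            a = astar_path(grid, (0, 0), (17, 21), SearchParams(alpha=alpha))
            # A* minimises alpha-weighted cost; terrain_cost is the
            # alpha-independent scale of the same quantity
            assert a.terrain_cost == pytest.approx(d.terrain_cost, rel=1e-9)


class TestPathMetrics:
    def test_road_km_closed_form(self):
        # 1 km of cardinal ROAD steps at 6 km/h is a 10-minute walk
        grid = uniform_grid(2, 101, land_class=LandClass.ROAD, cell_size_m=10.0)
        cells = [(0, c) for c in range(101)]
        p = Path.from_cells(grid, cells, CostTable())
        m = path_metrics(p, grid, SpeedTable())
        assert m.length_m == pytest.approx(1000.0)
        assert m.ideal_time_min == pytest.approx(10.0)

    def test_zero_length_path(self):
        grid = uniform_grid(3, 3)
        p = Path.from_cells(grid, [(1, 1)], CostTable())
        m = path_metrics(p, grid, SpeedTable())
        assert m.ideal_time_min == 0.0
        assert m.length_m == 0.0

    def test_mixed_path_manual_summation(self):
        # BARE cardinal, FOREST diagonal, ROAD cardinal: sum L / v by hand
        codes = np.array([[B, B, F, W], [B, F, R, R]], dtype=np.int8)
        grid = LandscapeGrid(codes, cell_size_m=11.0)
        cells = [(0, 0), (0, 1), (1, 2), (1, 3)]
        p = Path.from_cells(grid, cells, CostTable())
        m = path_metrics(p, grid, SpeedTable())
        v = SpeedTable().as_m_per_s()
        expect_s = 11.0 / v[B] + 11.0 * SQRT2 / v[R] + 11.0 / v[R]
        assert m.ideal_time_min == pytest.approx(expect_s / 60.0)
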