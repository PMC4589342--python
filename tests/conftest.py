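"""Shared fixtures: small, fast synthetic landscapes and hand-built grids."""

from __future__ import annotations

import numpy as np
import pytest

from waterwalk.landscape import (
    CostTable,
    LandClass,
    LandscapeGrid,
    Site,
    SiteSet,
    SpeedTable,
    SyntheticLandscapeConfig,
    generate_synthetic_landscape,
    river_adjacent_cells,
)

B, R, C, F, W = (
    LandClass.BARE,
    LandClass.ROAD,
    LandClass.CROP,
    LandClass.FOREST,
    LandClass.RIVER,
)


def small_config(seed: int = 0, **overrides) -> SyntheticLandscapeConfig:
    """A scaled-down landscape that generates in well under a second."""
    params = dict(
        n_rows=120,
        n_cols=200,
        river_sinuosity=0.25,
        road_offset_cells=10,
        forest_fraction=0.45,
        crop_fraction=0.3,
        patch_scale_cells=6,
        n_villages=6,
        n_boreholes=3,
        village_river_distance_cells=(12, 50),
        borehole_distance_band_km=(0.3, 1.2),
        riparian_belt_cells=(3, 10),
        seed=seed,
    )
    params.update(overrides)
    return SyntheticLandscapeConfig(**params)


@pytest.fixture(scope="session")
def small_landscape():
    return generate_synthetic_landscape(small_config(seed=0))


@pytest.fixture
def speed_table():
    return SpeedTable()


@pytest.fixture
def cost_table():
    return CostTable()


def uniform_grid(n_rows: int, n_cols: int, land_class=B, cell_size_m: float = 11.0) -> LandscapeGrid:
    return LandscapeGrid(
        np.full((n_rows, n_cols), int(land_class), dtype=np.int8), cell_size_m=cell_size_m
    )


def random_terrain_grid(rng: np.random.Generator, n_rows: int, n_cols: int,
                        river_prob: float = 0.0) -> LandscapeGrid:
    """Random passable mosaic with optional scattered river cells."""
    codes = rng.choice([int(B), int(R), int(C), int(F)], size=(n_rows, n_cols))
    if river_prob > 0:
        mask = rng.random((n_rows, n_cols)) < river_prob
        codes = np.where(mask, int(W), codes)
    # keep the corners passable so start/goal cells always exist
    codes[0, 0] = int(B)
    codes[-1, -1] = int(B)
    return LandscapeGrid(codes.astype(np.int8))


@pytest.fixture
def two_corridor_grid():
    """Two routes between west and east: a short corridor through forest and a
    longer corridor along a road, separated by impassable river rows."""
    n_rows, n_cols = 9, 21
    codes = np.full((n_rows, n_cols), int(W), dtype=np.int8)
    codes[4, :] = int(F)      # direct forest corridor
    codes[0, :] = int(R)      # road corridor along the top
    codes[1:4, 0] = int(B)    # western connector
    codes[1:4, -1] = int(B)   # eastern connector
    grid = LandscapeGrid(codes)
    start, goal = (4, 0), (4, n_cols - 1)
    return grid, start, goal


def octile_length_m(a, b, cell_size_m: float = 11.0) -> float:
    """Closed-form shortest 8-connected path length between two cells."""
    dr, dc = abs(a[0] - b[0]), abs(a[1] - b[1])
    lo, hi = min(dr, dc), max(dr, dc)
    return cell_size_m * (lo * np.sqrt(2.0) + (hi - lo))
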