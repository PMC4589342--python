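"""Land-cover grids, cost/speed tables, site tables and the synthetic landscape generator.

The model world is a rectangular raster of five land-cover classes at a fixed
cell size (11 m by default).  Each class carries a walking speed (km/h) and an
integer traversal cost; the river is the only impassable class and doubles as
the default water source, collected from land cells on its banks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path as FsPath
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "LandClass",
    "LandscapeGrid",
    "Site",
    "SiteSet",
    "SpeedTable",
    "CostTable",
    "SyntheticLandscapeConfig",
    "generate_synthetic_landscape",
    "river_adjacent_cells",
    "read_landscape",
    "write_landscape",
    "validate_sites",
    "LandscapeFormatError",
    "PlacementError",
]

NODATA = -9999


class LandscapeFormatError(ValueError):
    """Malformed raster or site file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class PlacementError(RuntimeError):
    """The synthetic generator could not satisfy a site-placement constraint."""


class LandClass(IntEnum):
    """Land-cover classes. Integer values are the on-disk raster codes."""

    BARE = 0
    ROAD = 1
    CROP = 2
    FOREST = 3
    RIVER = 4


#: classes an agent may stand on / walk through
PASSABLE = (LandClass.BARE, LandClass.ROAD, LandClass.CROP, LandClass.FOREST)


@dataclass(frozen=True)
class SpeedTable:
    """Walking speed (km/h) per land-cover class.

    Road is the fastest surface and forest/bush the slowest; the river is
    impassable so it has no speed.  Defaults follow the {4, 5, 6} km/h speed
    set with road=6 and forest=4.
    """

    road: float = 6.0
    bare: float = 5.0
    crop: float = 5.0
    forest: float = 4.0

    def __post_init__(self):
        vals = (self.road, self.bare, self.crop, self.forest)
        if any(v <= 0 for v in vals):
            raise ValueError("all walking speeds must be strictly positive")
        if self.road < max(vals):
            raise ValueError("ROAD must be the fastest class")
        if self.forest > min(vals):
            raise ValueError("FOREST must be the slowest class")

    def as_m_per_s(self) -> np.ndarray:
        """Speed per class code in m/s; NaN for the impassable river."""
        out = np.full(5, np.nan)
        kmh = {
            LandClass.BARE: self.bare,
            LandClass.ROAD: self.road,
            LandClass.CROP: self.crop,
            LandClass.FOREST: self.forest,
        }
        for cls, v in kmh.items():
            out[cls] = v * 1000.0 / 3600.0
        return out


@dataclass(frozen=True)
class CostTable:
    """Integer per-step traversal cost C per land-cover class.

    Costs rank classes in the reverse order of their walking speeds (road
    cheapest, forest/bush dearest) but deliberately exaggerate the contrast:
    they encode perceived effort and risk of a surface, not just pace, so
    dense bush — slow going, poor visibility, biting flies — is penalised far
    beyond its speed handicap.  The overall magnitude relative to the
    heuristic scale (10 per cell) sets where, in the cost-weighting sweep
    alpha = 0..45, routes transition from direct to terrain-avoiding.
    """

    road: int = 15
    bare: int = 38
    crop: int = 38
    forest: int = 90

    def __post_init__(self):
        vals = (self.road, self.bare, self.crop, self.forest)
        if any(v < 0 for v in vals):
            raise ValueError("costs must be non-negative")
        if self.road >= min(self.bare, self.crop, self.forest):
            raise ValueError("ROAD must be strictly the cheapest class")
        if self.forest <= max(self.road, self.bare, self.crop):
            raise ValueError("FOREST must be strictly the most expensive class")

    def as_array(self) -> np.ndarray:
        """Cost per class code; +inf marks the impassable river."""
        out = np.empty(5)
        out[LandClass.BARE] = self.bare
        out[LandClass.ROAD] = self.road
        out[LandClass.CROP] = self.crop
        out[LandClass.FOREST] = self.forest
        out[LandClass.RIVER] = np.inf
        return out

    def check_consistent_with(self, speeds: SpeedTable) -> None:
        """Costs must rank classes in the reverse order of their speeds."""
        pairs = [
            (self.road, speeds.road),
            (self.bare, speeds.bare),
            (self.crop, speeds.crop),
            (self.forest, speeds.forest),
        ]
        for (c1, s1) in pairs:
            for (c2, s2) in pairs:
                if s1 < s2 and c1 <= c2:
                    raise ValueError("cost ordering must be the reverse of speed ordering")


@dataclass
class LandscapeGrid:
    """A rectangular land-cover raster.

    ``classes`` holds LandClass codes (int8, rows x cols); row 0 is the
    northern edge.  Cell centres are the geometric reference: cardinal moves
    are ``cell_size_m`` long, diagonal moves ``cell_size_m * sqrt(2)``.
    """

    classes: np.ndarray
    cell_size_m: float = 11.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.classes = np.asarray(self.classes, dtype=np.int8)
        if self.classes.ndim != 2 or self.classes.size == 0:
            raise ValueError("grid must be a non-empty 2-D array")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        bad = ~np.isin(self.classes, [c.value for c in LandClass])
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise LandscapeFormatError(
                f"unknown land-class code {int(self.classes[r, c])} at cell ({r}, {c})"
            )

    @property
    def n_rows(self) -> int:
        return self.classes.shape[0]

    @property
    def n_cols(self) -> int:
        return self.classes.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape

    def is_inside(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols

    def passable_mask(self) -> np.ndarray:
        return self.classes != LandClass.RIVER

    def cell_center_xy(self, row: int, col: int) -> tuple[float, float]:
        """Metric coordinates of a cell centre (x east along cols, y north)."""
        x0, y0 = self.origin
        x = x0 + (col + 0.5) * self.cell_size_m
        y = y0 + (self.n_rows - row - 0.5) * self.cell_size_m
        return x, y


class Site(NamedTuple):
    id: str
    row: int
    col: int


@dataclass
class SiteSet:
    """Villages, boreholes and the river-bank cells that can serve as water sites."""

    villages: list[Site]
    boreholes: list[Site]
    riverine_candidates: list[tuple[int, int]] = field(default_factory=list)


def river_adjacent_cells(grid: LandscapeGrid) -> list[tuple[int, int]]:
    """All non-river cells with at least one river cell among their 8 neighbours.

    Returned in row-major order for determinism; empty if the grid has no river.
    """
    river = grid.classes == LandClass.RIVER
    if not river.any():
        return []
    near = ndimage.binary_dilation(river, structure=np.ones((3, 3), bool))
    bank = near & ~river
    return [tuple(rc) for rc in np.argwhere(bank)]


def validate_sites(grid: LandscapeGrid, sites: SiteSet) -> None:
    """Raise if any site-set invariant is violated on this grid."""
    for kind, entries in (("village", sites.villages), ("borehole", sites.boreholes)):
        for s in entries:
            if not grid.is_inside(s.row, s.col):
                raise LandscapeFormatError(f"{kind} {s.id!r} at ({s.row}, {s.col}) is outside the grid")
            if grid.classes[s.row, s.col] == LandClass.RIVER:
                raise LandscapeFormatError(f"{kind} {s.id!r} at ({s.row}, {s.col}) sits on a RIVER cell")
    if sites.riverine_candidates:
        bank = set(river_adjacent_cells(grid))
        for rc in sites.riverine_candidates:
            if tuple(rc) not in bank:
                raise LandscapeFormatError(
                    f"riverine candidate {tuple(rc)} is not a land cell adjacent to the river"
                )


# ---------------------------------------------------------------------------
# Synthetic landscape generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticLandscapeConfig:
    """Parameters of the generated river / road / mosaic / village / borehole layout.

    The defaults describe the package's standard study landscape: a
    360 x 600 grid of 11 m cells (4.0 km x 6.6 km) with a sinuous river
    running the length of the transect, a riparian bush belt of varying width
    (with gaps) along its banks, a road on the settled bank, a patchy
    forest/crop/bare mosaic, fourteen villages in a 0.3-2.2 km band from the
    river (one-way walk times span roughly the 4-45 minute range reported in
    rural water-collection surveys) and five boreholes whose nearest-village
    distances are spread across the borehole-threshold sweep range.
    """

    n_rows: int = 360
    n_cols: int = 600
    cell_size_m: float = 11.0
    river_sinuosity: float = 0.3
    road_offset_cells: int = 28
    forest_fraction: float = 0.50
    crop_fraction: float = 0.28
    patch_scale_cells: int = 12
    n_villages: int = 14
    n_boreholes: int = 5
    village_river_distance_cells: tuple[int, int] = (30, 200)
    borehole_distance_band_km: tuple[float, float] = (0.55, 2.5)
    riparian_belt_cells: tuple[int, int] = (15, 40)
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 10 or self.n_cols < 10:
            raise ValueError("grid must be at least 10 x 10")
        if not (0 <= self.forest_fraction and 0 <= self.crop_fraction):
            raise ValueError("fractions must be non-negative")
        if self.forest_fraction + self.crop_fraction > 1 + 1e-9:
            raise ValueError("forest_fraction + crop_fraction must not exceed 1")
        if self.river_sinuosity < 0:
            raise ValueError("river_sinuosity must be >= 0")
        if self.patch_scale_cells < 1:
            raise ValueError("patch_scale_cells must be a positive integer")
        lo, hi = self.village_river_distance_cells
        if not (0 < lo <= hi):
            raise ValueError("village_river_distance_cells must be an increasing positive pair")


def _river_course(cfg: SyntheticLandscapeConfig, rng: np.random.Generator) -> np.ndarray:
    """Centre row of the river per column: a random walk with momentum, kept in
    the lower part of the grid so the settled bank (smaller rows) stays connected."""
    lo = int(cfg.n_rows * 0.50)
    hi = int(cfg.n_rows * 0.92)
    row = np.empty(cfg.n_cols)
    r = rng.uniform(lo + 2, hi - 2)
    m = 0.0
    for c in range(cfg.n_cols):
        m = 0.9 * m + rng.normal(0.0, cfg.river_sinuosity)
        m = float(np.clip(m, -1.4, 1.4))
        r += m
        if r < lo:
            r, m = float(lo), abs(m)
        elif r > hi - 1:
            r, m = float(hi - 1), -abs(m)
        row[c] = r
    return row


def _paint_polyline(classes: np.ndarray, rows: np.ndarray, width: int, code: int,
                    only_over: np.ndarray | None = None) -> None:
    """Paint a column-spanning band. Vertical runs between consecutive columns are
    filled so the band is 4-connected (an 8-connected walker cannot slip through)."""
    n_rows, n_cols = classes.shape
    ri = np.clip(rows.astype(int), 0, n_rows - 1)
    for c in range(n_cols):
        top = ri[c] if c == 0 else min(ri[c - 1], ri[c])
        bot = (ri[c] if c == 0 else max(ri[c - 1], ri[c])) + width - 1
        top, bot = max(0, top), min(n_rows - 1, bot)
        seg = slice(top, bot + 1)
        if only_over is None:
            classes[seg, c] = code
        else:
            sel = only_over[seg, c]
            classes[seg, c][sel] = code


def _mosaic(cfg: SyntheticLandscapeConfig, rng: np.random.Generator) -> np.ndarray:
    """Patchy FOREST/CROP/BARE mosaic from thresholded smoothed noise."""
    noise = rng.standard_normal((cfg.n_rows, cfg.n_cols))
    smooth = ndimage.gaussian_filter(noise, sigma=cfg.patch_scale_cells, mode="nearest")
    # quantile thresholds give near-exact class fractions regardless of the
    # noise distribution after smoothing
    out = np.full((cfg.n_rows, cfg.n_cols), LandClass.BARE.value, dtype=np.int8)
    if cfg.forest_fraction > 0:
        qf = np.quantile(smooth, cfg.forest_fraction)
        out[smooth <= qf] = LandClass.FOREST
    if cfg.crop_fraction > 0:
        qf = np.quantile(smooth, cfg.forest_fraction)
        qc = np.quantile(smooth, min(1.0, cfg.forest_fraction + cfg.crop_fraction))
        out[(smooth > qf) & (smooth <= qc)] = LandClass.CROP
    return out


def generate_synthetic_landscape(
    cfg: SyntheticLandscapeConfig,
) -> tuple[LandscapeGrid, SiteSet]:
    """Generate a synthetic study landscape and its sites; deterministic given cfg.seed.

    Layout: one 8-connected river corridor spanning the grid west-east, a road
    running parallel on the settled (northern) bank, a smoothed-noise mosaic of
    forest/crop/bare patches, villages placed in a distance band from the
    river, and boreholes placed at controlled distances from villages so that
    borehole accessibility varies across the landscape.

    Raises :class:`PlacementError` when a site constraint cannot be met.
    """
    rng = np.random.default_rng(cfg.seed)
    classes = _mosaic(cfg, rng)

    river_rows = _river_course(cfg, rng)
    # the road follows the smoothed river trend, cutting across meanders
    # rather than tracking every bend
    trend = ndimage.gaussian_filter1d(river_rows, sigma=60, mode="nearest")
    road_rows = np.minimum(trend, river_rows - 3) - cfg.road_offset_cells
    # road first so the river always wins where they would collide
    _paint_polyline(classes, road_rows, 1, LandClass.ROAD)
    _paint_polyline(classes, river_rows, 2, LandClass.RIVER)

    river = classes == LandClass.RIVER
    dist_cells = ndimage.distance_transform_edt(~river)

    # riparian bush belt: dense thicket along the banks, of varying width,
    # pierced by a few narrow clear corridors down to the water (fords /
    # well-worn access paths)
    b_lo, b_hi = cfg.riparian_belt_cells
    if b_hi > 0:
        width_noise = ndimage.gaussian_filter(
            rng.standard_normal(cfg.n_cols), sigma=4 * cfg.patch_scale_cells, mode="nearest"
        )
        wn = (width_noise - width_noise.min()) / max(np.ptp(width_noise), 1e-12)
        belt_width = b_lo + (b_hi - b_lo) * wn  # per column
        corridor_noise = ndimage.gaussian_filter1d(
            rng.standard_normal(cfg.n_cols), sigma=1.5 * cfg.patch_scale_cells, mode="nearest"
        )
        gap_open = corridor_noise > np.quantile(corridor_noise, 0.88)  # ~12% of columns
        belt = (dist_cells <= belt_width[None, :]) & ~gap_open[None, :]
        belt &= (classes != LandClass.RIVER) & (classes != LandClass.ROAD)
        classes[belt] = LandClass.FOREST
        # the corridors themselves are kept walkable farmland/cleared land
        corridor = (dist_cells <= belt_width[None, :]) & gap_open[None, :]
        corridor &= (classes == LandClass.FOREST)
        classes[corridor] = LandClass.CROP

    grid = LandscapeGrid(classes, cell_size_m=cfg.cell_size_m)

    lo, hi = cfg.village_river_distance_cells
    north_of_river = np.zeros_like(river)
    for c in range(cfg.n_cols):
        top = int(np.argmax(river[:, c])) if river[:, c].any() else cfg.n_rows
        north_of_river[: max(0, top - 1), c] = True
    eligible = (
        north_of_river
        & (dist_cells >= lo)
        & (dist_cells <= hi)
        & (classes != LandClass.RIVER)
        & (classes != LandClass.ROAD)
    )
    cand = np.argwhere(eligible)
    if len(cand) < cfg.n_villages:
        raise PlacementError(
            f"only {len(cand)} cells eligible for {cfg.n_villages} villages"
        )
    order = rng.permutation(len(cand))
    min_sep = max(8.0, cfg.n_cols / (2.0 * max(cfg.n_villages, 1)))
    villages: list[Site] = []
    chosen: list[np.ndarray] = []
    for idx in order:
        rc = cand[idx]
        if all(np.hypot(*(rc - p)) >= min_sep for p in chosen):
            chosen.append(rc)
            villages.append(Site(f"v{len(villages):02d}", int(rc[0]), int(rc[1])))
            if len(villages) == cfg.n_villages:
                break
    if len(villages) < cfg.n_villages:
        raise PlacementError(
            f"could not place {cfg.n_villages} villages with separation {min_sep:.0f} cells"
        )
    villages.sort(key=lambda s: (s.row, s.col))
    villages = [Site(f"v{i:02d}", s.row, s.col) for i, s in enumerate(villages)]

    boreholes: list[Site] = []
    if cfg.n_boreholes > 0:
        # Boreholes are placed so that their nearest-village distances land on
        # targets spread across the configured band: borehole accessibility
        # then varies from village to village, which is what makes the
        # borehole threshold a meaningful axis of the landscape.  Each target
        # is anchored near a different stretch of the transect, and the cell
        # whose distance-to-nearest-village best matches the target is chosen
        # by direct search over the settled bank.
        d_lo, d_hi = cfg.borehole_distance_band_km
        if cfg.n_boreholes == 1:
            targets = [0.5 * (d_lo + d_hi)]
        else:
            targets = list(np.geomspace(max(d_lo, 1e-3), d_hi, cfg.n_boreholes))
        vill_rc = np.array([(s.row, s.col) for s in villages], dtype=float)
        rr, cc = np.mgrid[1 : cfg.n_rows - 1, 1 : cfg.n_cols - 1]
        d_vill = np.full(rr.shape, np.inf)
        for vr, vc in vill_rc:
            d_vill = np.minimum(d_vill, np.hypot(rr - vr, cc - vc))
        d_vill *= cfg.cell_size_m / 1000.0
        valid = north_of_river[1:-1, 1:-1] & (classes[1:-1, 1:-1] != LandClass.RIVER)
        anchors = sorted(villages, key=lambda s: s.col)
        anchor_sel = [anchors[(i * len(anchors)) // max(cfg.n_boreholes, 1)] for i in range(cfg.n_boreholes)]
        order = rng.permutation(cfg.n_boreholes)
        for i in range(cfg.n_boreholes):
            d_km = targets[order[i]]
            v = anchor_sel[i]
            reach = np.hypot(rr - v.row, cc - v.col) * cfg.cell_size_m / 1000.0
            local = valid & (reach <= 1.6 * d_km + 0.25)
            if not local.any():
                local = valid
            if not local.any():
                raise PlacementError("no cell available for borehole placement")
            score = np.where(local, np.abs(d_vill - d_km), np.inf)
            r, c = np.unravel_index(int(np.argmin(score)), score.shape)
            boreholes.append(Site(f"b{len(boreholes):02d}", int(r) + 1, int(c) + 1))
        boreholes.sort(key=lambda s: (s.row, s.col))
        boreholes = [Site(f"b{i:02d}", s.row, s.col) for i, s in enumerate(boreholes)]

    sites = SiteSet(
        villages=villages,
        boreholes=boreholes,
        riverine_candidates=river_adjacent_cells(grid),
    )
    validate_sites(grid, sites)
    return grid, sites


# ---------------------------------------------------------------------------
# I/O: ESRI ASCII raster + CSV site tables
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def write_grid_ascii(grid: LandscapeGrid, path: str | FsPath) -> None:
    """Write the grid as an ESRI ASCII raster of integer class codes."""
    x0, y0 = grid.origin
    lines = [
        f"ncols {grid.n_cols}",
        f"nrows {grid.n_rows}",
        f"xllcorner {x0:.6f}",
        f"yllcorner {y0:.6f}",
        f"cellsize {grid.cell_size_m:.6f}",
        f"NODATA_value {NODATA}",
    ]
    body = "\n".join(" ".join(str(int(v)) for v in row) for row in grid.classes)
    FsPath(path).write_text("\n".join(lines) + "\n" + body + "\n")


def read_grid_ascii(path: str | FsPath) -> LandscapeGrid:
    """Read an ESRI ASCII raster of land-class codes; errors name line numbers."""
    text = FsPath(path).read_text().splitlines()
    header: dict[str, float] = {}
    for i, key in enumerate(_HEADER_KEYS):
        if i >= len(text):
            raise LandscapeFormatError(f"missing header line for {key!r}", line=i + 1)
        parts = text[i].split()
        if len(parts) != 2 or parts[0].lower() != key:
            raise LandscapeFormatError(
                f"expected header '{key} <value>', got {text[i]!r}", line=i + 1
            )
        try:
            header[key] = float(parts[1])
        except ValueError:
            raise LandscapeFormatError(f"non-numeric header value {parts[1]!r}", line=i + 1)
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    rows: list[list[int]] = []
    for j, line in enumerate(text[6:], start=7):
        if not line.strip():
            continue
        try:
            vals = [int(tok) for tok in line.split()]
        except ValueError:
            raise LandscapeFormatError(f"non-integer raster value in {line!r}", line=j)
        if len(vals) != n_cols:
            raise LandscapeFormatError(
                f"expected {n_cols} columns, found {len(vals)}", line=j
            )
        for v in vals:
            if v != NODATA and v not in set(int(c) for c in LandClass):
                raise LandscapeFormatError(f"unknown land-class code {v}", line=j)
        rows.append(vals)
    if len(rows) != n_rows:
        raise LandscapeFormatError(
            f"expected {n_rows} raster rows, found {len(rows)}", line=len(text)
        )
    arr = np.array(rows, dtype=np.int8)
    return LandscapeGrid(
        arr,
        cell_size_m=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
    )


def _read_sites_csv(path: str | FsPath, grid: LandscapeGrid) -> list[Site]:
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"id", "row", "col"} <= cols:
        out = []
        for i, rec in enumerate(df.itertuples(index=False), start=2):
            row, col = rec.row, rec.col
            if float(row) != int(row) or float(col) != int(col):
                raise LandscapeFormatError(f"non-integer row/col for site {rec.id!r}", line=i)
            out.append(Site(str(rec.id), int(row), int(col)))
        return out
    if {"id", "x", "y"} <= cols:
        out = []
        x0, y0 = grid.origin
        for i, rec in enumerate(df.itertuples(index=False), start=2):
            col = int(round((rec.x - x0) / grid.cell_size_m - 0.5))
            row = int(round(grid.n_rows - 0.5 - (rec.y - y0) / grid.cell_size_m))
            out.append(Site(str(rec.id), row, col))
        return out
    raise LandscapeFormatError(
        f"site table {path} must have columns id,row,col or id,x,y", line=1
    )


def write_landscape(grid: LandscapeGrid, sites: SiteSet, out_dir: str | FsPath) -> dict[str, FsPath]:
    """Write raster + site CSVs into a directory; returns the paths written."""
    out = FsPath(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "raster": out / "landscape.asc",
        "villages": out / "villages.csv",
        "boreholes": out / "boreholes.csv",
    }
    write_grid_ascii(grid, paths["raster"])
    for key, entries in (("villages", sites.villages), ("boreholes", sites.boreholes)):
        pd.DataFrame(entries, columns=["id", "row", "col"]).to_csv(paths[key], index=False)
    return paths


def read_landscape(
    raster_file: str | FsPath,
    sites_files: Sequence[str | FsPath],
) -> tuple[LandscapeGrid, SiteSet]:
    """Read a raster plus (villages, boreholes) CSVs and validate all invariants.

    Riverine candidate cells are recomputed from the raster, so a
    write -> read round trip reproduces the grid and sites exactly.
    """
    grid = read_grid_ascii(raster_file)
    villages_file, boreholes_file = sites_files
    sites = SiteSet(
        villages=_read_sites_csv(villages_file, grid),
        boreholes=_read_sites_csv(boreholes_file, grid),
        riverine_candidates=river_adjacent_cells(grid),
    )
    validate_sites(grid, sites)
    return grid, sites
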