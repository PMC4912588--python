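"""Gridded time-in-area maps and core/home range extraction.

Time spent per 5x5 km cell is the utilisation measure: each regularised fix
contributes one sampling interval of residence to the cell containing it.
Per-bird maps are proportions of that bird's total at-sea time; the pooled
(population) map is the unweighted mean of per-bird proportions, so every
bird counts equally regardless of how many trips it made.

Ranges are cumulative-time cell sets: rank cells by time, take the smallest
top-ranked prefix holding at least the target share. The 50% set is the core
foraging area (CFA), the 95% set the home range area (HRA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import LocalProjection
from .trips import ColonySpec, Trip

# tolerance on the cumulative-weight threshold so that exact ties with the
# level (e.g. weights 0.5/0.5 at level 0.5) are not missed to rounding
_LEVEL_EPS = 1e-9

Cell = tuple[int, int]  # (row, col) = (floor(y/cell), floor(x/cell))


@dataclass(frozen=True)
class GridSpec:
    """Square analysis grid in the colony-centred plane.

    The colony sits exactly at a cell corner (the (0,0)/( -1,-1) corner), so
    cell (r, c) covers the half-open square
    [c*cell_km, (c+1)*cell_km) x [r*cell_km, (r+1)*cell_km) km east/north.
    """

    colony: ColonySpec
    cell_km: float = 5.0

    def __post_init__(self):
        if self.cell_km <= 0:
            raise ValueError("cell_km must be positive")

    @property
    def projection(self) -> LocalProjection:
        return self.colony.projection

    @property
    def cell_area_km2(self) -> float:
        return self.cell_km ** 2

    def cell_of(self, lon, lat) -> np.ndarray:
        """Map lon/lat arrays to (row, col) integer arrays."""
        x, y = self.projection.forward(lon, lat)
        row = np.floor(np.asarray(y) / self.cell_km).astype(np.int64)
        col = np.floor(np.asarray(x) / self.cell_km).astype(np.int64)
        return row, col

    def cell_polygon_lonlat(self, cell: Cell) -> list[tuple[float, float]]:
        """Closed lon/lat ring of one grid cell (counter-clockwise)."""
        r, c = cell
        xs = [c * self.cell_km, (c + 1) * self.cell_km]
        ys = [r * self.cell_km, (r + 1) * self.cell_km]
        corners = [(xs[0], ys[0]), (xs[1], ys[0]), (xs[1], ys[1]), (xs[0], ys[1]), (xs[0], ys[0])]
        return [tuple(map(float, self.projection.inverse(x, y))) for x, y in corners]


@dataclass
class TimeInAreaMap:
    """Proportion of at-sea time per grid cell for one bird (or pooled)."""

    owner: str
    weights: dict[Cell, float] = field(repr=False)
    grid: GridSpec = None

    def __post_init__(self):
        if self.weights:
            total = sum(self.weights.values())
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError(f"weights must sum to 1, got {total!r}")
            if min(self.weights.values()) < 0:
                raise ValueError("weights must be non-negative")

    def __len__(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class RangeSet:
    """The cell set of a cumulative time-use range and its area."""

    level: float
    cells: frozenset[Cell]
    cell_km: float

    @property
    def area_km2(self) -> float:
        return self.cell_km ** 2 * len(self.cells)

    def __len__(self) -> int:
        return len(self.cells)


def bird_time_map(trips: list[Trip], grid: GridSpec, owner: str | None = None) -> TimeInAreaMap:
    """Time-in-area map from one bird's (interpolated, foraging) trips.

    Each fix stands for one sampling interval of residence in its cell;
    with a regular interval the per-cell proportion is simply the fix count
    divided by the bird's total at-sea fix count.
    """
    if not trips:
        raise ValueError("no trips: cannot build a time-in-area map")
    birds = {t.bird_id for t in trips}
    if owner is None:
        if len(birds) != 1:
            raise ValueError(f"trips of multiple birds {birds}; pass owner explicitly")
        owner = next(iter(birds))
    rows, cols = [], []
    for t in trips:
        r, c = grid.cell_of(t.fixes["lon"].to_numpy(), t.fixes["lat"].to_numpy())
        rows.append(r)
        cols.append(c)
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    cells, counts = np.unique(np.stack([r, c], axis=1), axis=0, return_counts=True)
    total = counts.sum()
    weights = {(int(rr), int(cc)): cnt / total for (rr, cc), cnt in zip(cells, counts)}
    return TimeInAreaMap(owner=owner, weights=weights, grid=grid)


def pool_maps(maps: list[TimeInAreaMap], owner: str = "pooled") -> TimeInAreaMap:
    """Unweighted mean of per-bird proportion maps (equal weight per bird)."""
    if not maps:
        raise ValueError("no maps to pool")
    n = len(maps)
    pooled: dict[Cell, float] = {}
    for m in maps:
        for cell, w in m.weights.items():
            pooled[cell] = pooled.get(cell, 0.0) + w / n
    return TimeInAreaMap(owner=owner, weights=pooled, grid=maps[0].grid)


def extract_range(tmap: TimeInAreaMap, level: float) -> RangeSet:
    """Smallest top-ranked cell set holding at least ``level`` of the time.

    Cells are ranked by weight descending, ties broken by ascending (row,
    col); the prefix stops at the cell whose cumulative weight first reaches
    the level (that crossing cell is included, so coverage >= level).
    """
    if not (0.0 < level <= 1.0):
        raise ValueError("level must be in (0, 1]")
    if not tmap.weights:
        raise ValueError("empty map")
    items = sorted(tmap.weights.items(), key=lambda kv: (-kv[1], kv[0]))
    cum = 0.0
    chosen: list[Cell] = []
    for cell, w in items:
        chosen.append(cell)
        cum += w
        if cum >= level - _LEVEL_EPS:
            break
    cell_km = tmap.grid.cell_km if tmap.grid is not None else 5.0
    return RangeSet(level=level, cells=frozenset(chosen), cell_km=cell_km)
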