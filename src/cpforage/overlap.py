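"""Overlap statistics: between years, between individuals, and with
external polygons (e.g. proposed windfarm footprints).

The directional sample overlap between year X and year Y is the percentage
of X's range cells also in Y's range. Because each year's sample covers only
part of the population-level range, the sample overlap understates the true
one; under equal detection in overlapping and non-overlapping cells it is
corrected by the second year's sampled proportion S (in %):

    population overlap = O * 100 / S

Values slightly above 100% can arise from the extrapolation and are
reported as computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import shape as shapely_shape

from .spaceuse import Cell, RangeSet
from .trips import Trip


def sample_overlap(cells_x: RangeSet, cells_y: RangeSet) -> float:
    """Percentage of X's range cells that fall inside Y's range.

    Directional: sample_overlap(X, Y) != sample_overlap(Y, X) in general.
    """
    if cells_x.cell_km != cells_y.cell_km:
        raise ValueError("range sets are on different grids")
    if cells_x.level != cells_y.level:
        raise ValueError("range sets are at different levels")
    if not cells_x.cells:
        raise ValueError("empty X range")
    return 100.0 * len(cells_x.cells & cells_y.cells) / len(cells_x.cells)


def population_overlap(o_percent: float, s_y2_percent: float) -> float:
    """Correct a sample overlap O (%) for the incompleteness of the second
    year's sample, whose sampled proportion is S (%)."""
    if not (0.0 <= o_percent <= 100.0):
        raise ValueError("sample overlap must be within [0, 100] %")
    if s_y2_percent <= 0:
        raise ValueError("sampled proportion S must be positive")
    return o_percent * 100.0 / s_y2_percent


@dataclass(frozen=True)
class CellUsage:
    """Per-cell usage counts across birds (within a year) or years."""

    counts: dict[Cell, int]
    n_owners: int

    def histogram(self) -> dict[int, int]:
        """Number of cells used by exactly k owners, for k = 1..n_owners."""
        hist = {k: 0 for k in range(1, self.n_owners + 1)}
        for c in self.counts.values():
            hist[c] += 1
        return hist


def _count_usage(range_sets: list[RangeSet]) -> CellUsage:
    counts: dict[Cell, int] = {}
    for rs in range_sets:
        for cell in rs.cells:
            counts[cell] = counts.get(cell, 0) + 1
    return CellUsage(counts=counts, n_owners=len(range_sets))


def bird_count_per_cell(bird_ranges: dict[str, RangeSet]) -> CellUsage:
    """How many birds include each cell in their individual range."""
    if not bird_ranges:
        raise ValueError("no bird ranges")
    return _count_usage(list(bird_ranges.values()))


def year_count_per_cell(year_ranges: dict[object, RangeSet]) -> CellUsage:
    """How many years include each cell in the pooled range."""
    if not year_ranges:
        raise ValueError("no yearly ranges")
    return _count_usage(list(year_ranges.values()))


def load_polygons(source) -> list[tuple[str, shapely.Geometry]]:
    """Read (name, polygon) pairs from a GeoJSON FeatureCollection.

    ``source`` may be a path or an already-parsed mapping. Invalid
    geometries raise, naming the offending feature.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "read"):
        with open(source) as fh:
            gj = json.load(fh)
    else:
        gj = source
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    out = []
    for i, feat in enumerate(feats):
        name = str(feat.get("properties", {}).get("name", f"feature_{i}"))
        geom = shapely_shape(feat["geometry"])
        if not geom.is_valid:
            raise ValueError(f"invalid polygon geometry in feature '{name}'")
        out.append((name, geom))
    return out


@dataclass(frozen=True)
class ExposureCounts:
    """Trips/birds whose tracks enter any of the assessed polygons."""

    n_trips_total: int
    n_trips_hit: int
    n_birds_total: int
    n_birds_hit: int

    @property
    def pct_trips(self) -> int:
        return int(round(100.0 * self.n_trips_hit / self.n_trips_total)) if self.n_trips_total else 0

    @property
    def pct_birds(self) -> int:
        return int(round(100.0 * self.n_birds_hit / self.n_birds_total)) if self.n_birds_total else 0


def polygon_intersections(
    trips: list[Trip],
    polygons,
    colony=None,
    refine_interval_s: float | None = None,
) -> ExposureCounts:
    """Count trips and birds with at least one fix strictly inside any polygon.

    Polygons are (name, geometry) pairs in lon/lat (see ``load_polygons``) or
    bare geometries. Fix-in-polygon at the sampling resolution defines
    intersection; pass ``refine_interval_s`` (with ``colony``) to
    re-interpolate tracks to a finer step first, which catches edge-on
    crossings between fixes.
    """
    geoms = [p[1] if isinstance(p, tuple) else p for p in polygons]
    for i, g in enumerate(geoms):
        if not g.is_valid:
            name = polygons[i][0] if isinstance(polygons[i], tuple) else f"feature_{i}"
            raise ValueError(f"invalid polygon geometry in feature '{name}'")
    union = shapely.unary_union(geoms) if geoms else None
    hit_birds: set[str] = set()
    n_hit = 0
    for trip in trips:
        fixes = trip.fixes
        if refine_interval_s is not None:
            from .trips import interpolate

            fixes = interpolate(fixes, interval_s=refine_interval_s, colony=colony)
        inside = (
            shapely.contains_xy(union, fixes["lon"].to_numpy(), fixes["lat"].to_numpy())
            if union is not None
            else np.zeros(len(fixes), dtype=bool)
        )
        if inside.any():
            n_hit += 1
            hit_birds.add(trip.bird_id)
    birds = {t.bird_id for t in trips}
    return ExposureCounts(
        n_trips_total=len(trips),
        n_trips_hit=n_hit,
        n_birds_total=len(birds),
        n_birds_hit=len(hit_birds),
    )
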