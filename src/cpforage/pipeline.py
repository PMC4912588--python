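"""End-to-end orchestration: read fixes, run one year's analysis, compare years.

``run_year`` chains the whole method: interpolate each bird's series to 10 s,
segment trips at the colony buffer, drop loafing excursions (<= 40 min),
compute trip metrics, build per-bird and pooled 5x5 km time-in-area maps,
extract 50% (CFA) and 95% (HRA) ranges, bootstrap the accumulation curve and
Michaelis-Menten extrapolation, fit per-bird trip-consistency indices, and
count trips/birds entering any supplied polygon footprints. ``compare_years``
derives directional sample and population-corrected overlaps between bundles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import overlap as ov
from .represent import (IndividualConsistency, RepresentativenessSummary,
                        individual_consistency, representativeness_summary)
from .spaceuse import GridSpec, RangeSet, TimeInAreaMap, bird_time_map, extract_range, pool_maps
from .trips import (ColonySpec, Trip, filter_foraging, interpolate, segment_trips,
                    summarize_by_year, trip_metrics_table)

logger = logging.getLogger(__name__)

#: Les Etacs, Alderney — the study colony used as default.
LES_ETACS = ColonySpec(lon=-2.239, lat=49.705, buffer_m=30.0)


@dataclass(frozen=True)
class YearContext:
    """Per-year metadata carried alongside the computed results."""

    year: object
    breeding_success_p: float | None = None  # chicks fledged per pair
    nao_june: float | None = None  # June North Atlantic Oscillation index
    population_n: int = 10_000

    def __post_init__(self):
        if self.population_n <= 0:
            raise ValueError("population_n must be positive")


@dataclass(frozen=True)
class RunConfig:
    """All thresholds and knobs of one analysis run."""

    colony: ColonySpec = LES_ETACS
    cell_km: float = 5.0
    interval_s: float = 10.0
    min_trip_min: float = 40.0
    levels: tuple[float, ...] = (0.5, 0.95)
    n_boot: int = 10_000
    consistency_n_boot: int = 1_000
    population_n: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.interval_s <= 0 or self.min_trip_min <= 0 or self.n_boot < 1:
            raise ValueError("thresholds must be positive")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(colony=self.colony, cell_km=self.cell_km)


def read_fixes(path) -> pd.DataFrame:
    """Read and validate a fix CSV (columns bird_id, timestamp, lat, lon).

    Timestamps are parsed as ISO-8601 and normalised to UTC. Rows out of
    time order are sorted (with a warning); duplicate timestamps within a
    bird, malformed timestamps and out-of-range coordinates are rejected
    with the offending line number (1-based, header = line 1).
    """
    df = pd.read_csv(path, dtype={"bird_id": str})
    required = {"bird_id", "timestamp", "lat", "lon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s) {sorted(missing)} in {path}")
    times = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    if times.isna().any():
        line = int(times.index[times.isna()][0]) + 2
        raise ValueError(f"malformed timestamp at line {line}: {df['timestamp'].iloc[line - 2]!r}")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    bad = lat.isna() | lon.isna() | (lat.abs() > 90) | (lon.abs() > 180)
    if bad.any():
        line = int(bad.index[bad][0]) + 2
        raise ValueError(
            f"coordinate out of range at line {line}: lat={df['lat'].iloc[line - 2]!r} "
            f"lon={df['lon'].iloc[line - 2]!r}"
        )
    out = pd.DataFrame({"bird_id": df["bird_id"], "time": times, "lon": lon, "lat": lat})
    if not out.groupby("bird_id", sort=False)["time"].is_monotonic_increasing.all():
        logger.warning("%s: fixes out of time order; sorting per bird", path)
    out = out.sort_values(["bird_id", "time"], kind="mergesort").reset_index(drop=True)
    dup = out.duplicated(subset=["bird_id", "time"])
    if dup.any():
        row = out[dup].iloc[0]
        raise ValueError(f"duplicate timestamp {row['time']} for bird {row['bird_id']}")
    return out


@dataclass
class YearBundle:
    """Everything computed for one year."""

    context: YearContext
    config: RunConfig
    trips: dict[str, list[Trip]] = field(repr=False)  # foraging trips per bird
    metrics: pd.DataFrame = field(repr=False)
    bird_maps: dict[str, TimeInAreaMap] = field(repr=False)
    pooled_map: TimeInAreaMap = field(repr=False)
    ranges: dict[float, RangeSet]  # pooled, per level
    bird_ranges: dict[float, dict[str, RangeSet]]  # per level, per bird
    represent: dict[float, RepresentativenessSummary]
    consistency: dict[float, list[IndividualConsistency]]
    exposure: ov.ExposureCounts | None = None

    @property
    def year(self):
        return self.context.year


def run_year(
    config: RunConfig,
    fixes: pd.DataFrame,
    context: YearContext | object = None,
    polygons=None,
    seed: int | None = None,
) -> YearBundle:
    """Run the whole per-year analysis on one year's raw fixes."""
    if context is None or not isinstance(context, YearContext):
        context = YearContext(year=context if context is not None else "year",
                              population_n=config.population_n)
    grid = config.grid
    rng = np.random.default_rng(config.seed if seed is None else seed)

    trips_by_bird: dict[str, list[Trip]] = {}
    all_trips: list[Trip] = []
    for bird, bf in fixes.groupby("bird_id", sort=True):
        if len(bf) < 2:
            logger.warning("bird %s: fewer than 2 fixes; skipped", bird)
            continue
        regular = interpolate(bf.reset_index(drop=True), interval_s=config.interval_s,
                              colony=config.colony)
        segs = segment_trips(regular, config.colony)
        foraging = filter_foraging(segs, min_duration_min=config.min_trip_min)
        logger.info("year %s bird %s: %d excursions, %d foraging trips",
                    context.year, bird, len(segs), len(foraging))
        if foraging:
            trips_by_bird[bird] = foraging
            all_trips.extend(foraging)
    if not trips_by_bird:
        raise RuntimeError(f"[trips] no foraging trips found for year {context.year}")

    metrics = trip_metrics_table(all_trips, config.colony)
    metrics.insert(0, "year", context.year)

    bird_maps = {b: bird_time_map(ts, grid) for b, ts in trips_by_bird.items()}
    pooled = pool_maps(list(bird_maps.values()), owner=f"pooled_{context.year}")

    ranges: dict[float, RangeSet] = {}
    bird_ranges: dict[float, dict[str, RangeSet]] = {}
    represent: dict[float, RepresentativenessSummary] = {}
    consistency: dict[float, list[IndividualConsistency]] = {}
    maps_in_order = [bird_maps[b] for b in sorted(bird_maps)]
    for level in config.levels:
        ranges[level] = extract_range(pooled, level)
        bird_ranges[level] = {b: extract_range(m, level) for b, m in bird_maps.items()}
        if len(maps_in_order) >= 2:
            represent[level] = representativeness_summary(
                maps_in_order, level=level, n_boot=config.n_boot, rng=rng,
                population_n=context.population_n,
            )
        cons = []
        for b in sorted(trips_by_bird):
            res = individual_consistency(trips_by_bird[b], grid, level=level,
                                         n_boot=config.consistency_n_boot, rng=rng)
            if res is not None:
                cons.append(res)
        consistency[level] = cons

    exposure = None
    if polygons is not None:
        exposure = ov.polygon_intersections(all_trips, polygons)

    return YearBundle(
        context=context, config=config, trips=trips_by_bird, metrics=metrics,
        bird_maps=bird_maps, pooled_map=pooled, ranges=ranges, bird_ranges=bird_ranges,
        represent=represent, consistency=consistency, exposure=exposure,
    )


def overlap_matrix(bundles: list[YearBundle], level: float) -> pd.DataFrame:
    """Directional overlaps for every ordered year pair at one range level.

    O is the sample overlap of year X's cells onto year Y's; the population
    correction divides by year Y's sampled proportion (in %) at the same
    level.
    """
    rows = []
    for bx in bundles:
        for by in bundles:
            if bx.year == by.year:
                continue
            o = ov.sample_overlap(bx.ranges[level], by.ranges[level])
            s_y2 = by.represent[level].prop_sampled * 100.0 if level in by.represent else np.nan
            pop = ov.population_overlap(o, s_y2) if np.isfinite(s_y2) else np.nan
            rows.append({
                "level": level, "year_x": bx.year, "year_y": by.year,
                "sample_overlap_pct": o, "s_y2_pct": s_y2, "population_overlap_pct": pop,
            })
    return pd.DataFrame(rows)


def compare_years(bundles: list[YearBundle]) -> dict:
    """All pairwise overlap tables, per-cell year counts and metric summaries."""
    if len(bundles) < 2:
        raise ValueError("need at least 2 year bundles")
    cells = {b.config.cell_km for b in bundles}
    colonies = {(b.config.colony.lon, b.config.colony.lat) for b in bundles}
    if len(cells) > 1 or len(colonies) > 1:
        raise ValueError("bundles are on different grids")
    levels = bundles[0].config.levels
    overlaps = pd.concat([overlap_matrix(bundles, lv) for lv in levels], ignore_index=True)
    year_counts = {
        lv: ov.year_count_per_cell({b.year: b.ranges[lv] for b in bundles}) for lv in levels
    }
    summary = summarize_by_year(pd.concat([b.metrics for b in bundles], ignore_index=True))
    return {"overlaps": overlaps, "year_cell_counts": year_counts, "metric_summary": summary}


# ---------------------------------------------------------------------------
# bundle serialisation

def _range_geojson(rs: RangeSet, grid: GridSpec) -> dict:
    feats = []
    for cell in sorted(rs.cells):
        ring = grid.cell_polygon_lonlat(cell)
        feats.append({
            "type": "Feature",
            "properties": {"row": cell[0], "col": cell[1], "level": rs.level},
            "geometry": {"type": "Polygon", "coordinates": [[list(pt) for pt in ring]]},
        })
    return {"type": "FeatureCollection", "features": feats}


def write_bundle(bundle: YearBundle, outdir) -> None:
    """Write one year's tables (CSV, units in column names) and GeoJSON layers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    year = bundle.year
    ff = "%.6f"
    bundle.metrics.to_csv(outdir / f"trip_metrics_{year}.csv", index=False, float_format=ff)

    rows = []
    for level, summ in bundle.represent.items():
        rows.append({
            "year": year, "level": level, "n_birds": summ.n_birds,
            "mm_a_km2": summ.fit.a, "mm_b_individuals": summ.fit.b,
            "sample_area_km2": summ.sample_area_km2,
            "population_n": summ.population_n,
            "predicted_population_area_km2": summ.predicted_population_area_km2,
            "prop_sampled": summ.prop_sampled, "n_for_95pct": summ.n_for_95pct,
        })
    pd.DataFrame(rows).to_csv(outdir / f"representativeness_{year}.csv", index=False,
                              float_format=ff)

    rows = []
    for level, cons in bundle.consistency.items():
        for c in cons:
            rows.append({
                "year": year, "level": level, "bird_id": c.bird_id, "n_trips": c.n_trips,
                "mm_a_km2": c.fit.a, "mm_b_trips": c.fit.b,
            })
    pd.DataFrame(rows, columns=["year", "level", "bird_id", "n_trips", "mm_a_km2",
                                "mm_b_trips"]).to_csv(
        outdir / f"individual_consistency_{year}.csv", index=False, float_format=ff)

    cell_rows = []
    for level, rs in bundle.ranges.items():
        for r, c in sorted(rs.cells):
            cell_rows.append({"year": year, "level": level, "row": r, "col": c,
                              "cell_km": rs.cell_km})
        with open(outdir / f"range_{int(level * 100)}_{year}.geojson", "w") as fh:
            json.dump(_range_geojson(rs, bundle.config.grid), fh)
    pd.DataFrame(cell_rows).to_csv(outdir / f"range_cells_{year}.csv", index=False)

    if bundle.exposure is not None:
        e = bundle.exposure
        pd.DataFrame([{
            "year": year,
            "n_birds_windfarm": e.n_birds_hit, "n_birds_total": e.n_birds_total,
            "pct_birds": e.pct_birds,
            "n_trips_windfarm": e.n_trips_hit, "n_trips_total": e.n_trips_total,
            "pct_trips": e.pct_trips,
        }]).to_csv(outdir / f"windfarm_exposure_{year}.csv", index=False)

    with open(outdir / f"config_{year}.json", "w") as fh:
        json.dump({"config": asdict(bundle.config), "context": asdict(bundle.context)},
                  fh, indent=2, default=str)
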