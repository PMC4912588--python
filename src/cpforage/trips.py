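"""Track regularisation, colony-based trip segmentation and trip metrics.

A GPS deployment yields an irregular fix series per bird (nominal 2-min
logging, with gaps from diving and missed locks). The pipeline here:

1. ``interpolate`` — resample each bird's series to a regular 10-s step by
   linear interpolation in the colony-centred plane;
2. ``segment_trips`` — cut the series into excursions at crossings of a
   small buffer (default 30 m) around the colony;
3. ``filter_foraging`` — drop "loafing" excursions of 40 min or less;
4. ``compute_trip_metrics`` — duration, path length, maximum displacement
   from the colony and directness (length / max displacement; 2 means a
   straight out-and-back track).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import LocalProjection, haversine_km, path_length_km

logger = logging.getLogger(__name__)

FIX_COLUMNS = ["bird_id", "time", "lon", "lat"]


@dataclass(frozen=True)
class ColonySpec:
    """Colony location (degrees) with the buffer radius separating 'at colony'
    from 'at sea'. Default is a 30 m buffer."""

    lon: float
    lat: float
    buffer_m: float = 30.0

    def __post_init__(self):
        if self.buffer_m <= 0:
            raise ValueError("buffer_m must be positive")
        if not (-90 <= self.lat <= 90 and -180 <= self.lon <= 180):
            raise ValueError("colony coordinates out of range")

    @property
    def projection(self) -> LocalProjection:
        return LocalProjection(self.lon, self.lat)


@dataclass
class Trip:
    """One excursion outside the colony buffer.

    ``complete`` is False when the excursion is still open at either end of
    the recorded series (departure or return unobserved); incomplete trips
    are excluded from metrics and space use by default.
    """

    bird_id: str
    trip_index: int
    fixes: pd.DataFrame = field(repr=False)
    start_time: pd.Timestamp = None
    end_time: pd.Timestamp = None
    complete: bool = True

    def __post_init__(self):
        if self.start_time is None:
            self.start_time = self.fixes["time"].iloc[0]
        if self.end_time is None:
            self.end_time = self.fixes["time"].iloc[-1]

    @property
    def duration_h(self) -> float:
        return (self.end_time - self.start_time).total_seconds() / 3600.0

    @property
    def duration_min(self) -> float:
        return self.duration_h * 60.0

    def __len__(self) -> int:
        return len(self.fixes)


@dataclass(frozen=True)
class TripMetrics:
    bird_id: str
    trip_index: int
    duration_h: float
    length_km: float
    max_distance_km: float
    directness: float  # NaN when max_distance is zero


def _check_single_bird(fixes: pd.DataFrame) -> str:
    birds = fixes["bird_id"].unique()
    if len(birds) != 1:
        raise ValueError(f"expected fixes of a single bird, got {list(birds)}")
    return birds[0]


def interpolate(
    fixes: pd.DataFrame,
    interval_s: float = 10.0,
    colony: ColonySpec | None = None,
    max_gap_warn_min: float = 30.0,
) -> pd.DataFrame:
    """Resample one bird's fixes to a regular ``interval_s`` grid.

    Positions are linearly interpolated in a local planar frame (centred on
    the colony if given, else on the track mean) and converted back to
    lon/lat. The grid runs from the first fix time in steps of ``interval_s``;
    the final original time and position are always retained, so the first
    and last fixes of the output equal the originals. Gaps longer than
    ``max_gap_warn_min`` are interpolated like any other but logged.
    """
    if len(fixes) < 2:
        raise ValueError("interpolation needs at least 2 fixes")
    if interval_s <= 0:
        raise ValueError("interval_s must be positive")
    bird = _check_single_bird(fixes)
    sec = (fixes["time"] - fixes["time"].iloc[0]).dt.total_seconds().to_numpy()
    dt = np.diff(sec)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        raise ValueError(
            f"non-monotone timestamps for bird {bird}: record {i + 1} at {fixes['time'].iloc[i + 1]}"
        )
    if np.any(dt > max_gap_warn_min * 60.0):
        n_long = int(np.sum(dt > max_gap_warn_min * 60.0))
        logger.warning(
            "bird %s: interpolating across %d gap(s) longer than %.0f min (longest %.1f min)",
            bird, n_long, max_gap_warn_min, dt.max() / 60.0,
        )

    if colony is not None:
        proj = colony.projection
    else:
        proj = LocalProjection(float(fixes["lon"].mean()), float(fixes["lat"].mean()))
    x, y = proj.forward(fixes["lon"].to_numpy(), fixes["lat"].to_numpy())

    total = sec[-1]
    grid = np.arange(0.0, total + interval_s * 0.5, interval_s)
    if grid[-1] > total:
        grid = grid[:-1]
    if grid[-1] < total:  # keep the true last fix
        grid = np.append(grid, total)
    xi = np.interp(grid, sec, x)
    yi = np.interp(grid, sec, y)
    lon_i, lat_i = proj.inverse(xi, yi)
    times = fixes["time"].iloc[0] + pd.to_timedelta(np.round(grid * 1e9).astype(np.int64), unit="ns")
    return pd.DataFrame({"bird_id": bird, "time": times, "lon": lon_i, "lat": lat_i})


def segment_trips(fixes: pd.DataFrame, colony: ColonySpec) -> list[Trip]:
    """Cut one bird's (interpolated) series into excursions outside the buffer.

    A trip is a maximal run of consecutive fixes strictly farther than the
    buffer from the colony. Runs open at the start or end of the series are
    flagged incomplete. Trip indices are 1-based in time order.
    """
    bird = _check_single_bird(fixes)
    d_km = haversine_km(fixes["lon"].to_numpy(), fixes["lat"].to_numpy(), colony.lon, colony.lat)
    outside = d_km > colony.buffer_m / 1000.0
    trips: list[Trip] = []
    if not outside.any():
        return trips
    # run boundaries of the boolean mask
    idx = np.flatnonzero(np.diff(np.concatenate(([False], outside, [False])).astype(np.int8)))
    starts, ends = idx[::2], idx[1::2]  # [start, end) index pairs
    for k, (s, e) in enumerate(zip(starts, ends), start=1):
        seg = fixes.iloc[s:e].reset_index(drop=True)
        complete = not (s == 0 or e == len(fixes))
        trips.append(Trip(bird_id=bird, trip_index=k, fixes=seg, complete=complete))
    return trips


def filter_foraging(
    trips: list[Trip],
    min_duration_min: float = 40.0,
    include_incomplete: bool = False,
) -> list[Trip]:
    """Keep foraging trips: strictly longer than ``min_duration_min``.

    Shorter excursions are loafing near the colony (or post-disturbance
    flights) and are discarded. Incomplete trips are dropped unless asked for.
    """
    kept = [
        t for t in trips
        if t.duration_min > min_duration_min and (include_incomplete or t.complete)
    ]
    n_loaf = sum(1 for t in trips if t.duration_min <= min_duration_min)
    logger.info("foraging filter: %d trips in, %d kept, %d loafing excursions removed",
                len(trips), len(kept), n_loaf)
    return kept


def compute_trip_metrics(trip: Trip, colony: ColonySpec) -> TripMetrics:
    """Duration (h), great-circle path length (km), maximum colony distance
    (km) and directness for one trip."""
    if len(trip) < 2:
        raise ValueError("trip metrics need at least 2 fixes")
    lon = trip.fixes["lon"].to_numpy()
    lat = trip.fixes["lat"].to_numpy()
    length = path_length_km(lon, lat)
    max_d = float(np.max(haversine_km(lon, lat, colony.lon, colony.lat)))
    directness = length / max_d if max_d > 0 else float("nan")
    return TripMetrics(
        bird_id=trip.bird_id,
        trip_index=trip.trip_index,
        duration_h=trip.duration_h,
        length_km=length,
        max_distance_km=max_d,
        directness=directness,
    )


def trip_metrics_table(trips: list[Trip], colony: ColonySpec) -> pd.DataFrame:
    """Metrics for a list of trips as a tidy table (one row per trip)."""
    rows = [compute_trip_metrics(t, colony).__dict__ for t in trips]
    cols = ["bird_id", "trip_index", "duration_h", "length_km", "max_distance_km", "directness"]
    return pd.DataFrame(rows, columns=cols)


def summarize_by_year(metrics: pd.DataFrame, year_col: str = "year") -> pd.DataFrame:
    """Per-year arithmetic mean and standard error of each trip metric.

    Returns a table with one row per (year, metric) and columns mean / se / n.
    SE is NaN for a single trip.
    """
    value_cols = [c for c in ("duration_h", "length_km", "max_distance_km", "directness")
                  if c in metrics.columns]
    out = []
    for year, grp in metrics.groupby(year_col, sort=True):
        for c in value_cols:
            v = grp[c].dropna()
            out.append({
                year_col: year, "metric": c,
                "mean": v.mean(), "se": v.sem(), "n": int(v.size),
            })
    return pd.DataFrame(out)
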