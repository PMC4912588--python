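"""Shared fixtures: small synthetic deployments and hand-built tracks."""

import numpy as np
import pandas as pd
import pytest

import cpforage as cpf


@pytest.fixture(scope="session")
def colony():
    return cpf.ColonySpec(lon=-2.239, lat=49.705, buffer_m=30.0)


@pytest.fixture(scope="session")
def grid(colony):
    return cpf.GridSpec(colony=colony, cell_km=5.0)


@pytest.fixture(scope="session")
def small_dataset():
    """6 birds x 4 excursions, low-resource/high-patchiness scenario."""
    scenario = cpf.scenario_preset("low", "high", seed=42)
    return cpf.simulate_population(scenario, n_birds=6, trips_per_bird=4)


@pytest.fixture(scope="session")
def small_foraging_trips(small_dataset):
    """Interpolated, loafing-filtered trips per bird for the small dataset."""
    out = {}
    for bird, bf in small_dataset.fixes.groupby("bird_id"):
        reg = cpf.interpolate(bf.reset_index(drop=True), interval_s=10,
                              colony=small_dataset.colony)
        segs = cpf.segment_trips(reg, small_dataset.colony)
        trips = cpf.filter_foraging(segs)
        if trips:
            out[bird] = trips
    return out


@pytest.fixture(scope="session")
def small_bird_maps(small_foraging_trips, small_dataset):
    g = cpf.GridSpec(colony=small_dataset.colony, cell_km=5.0)
    return {b: cpf.bird_time_map(ts, g) for b, ts in small_foraging_trips.items()}


def planar_track(colony, xy_km, start="2015-06-10T06:00:00Z", interval_s=120):
    """Build a single-bird fix frame from planar km offsets around a colony."""
    proj = colony.projection
    xy = np.asarray(xy_km, dtype=float)
    lon, lat = proj.inverse(xy[:, 0], xy[:, 1])
    t0 = pd.Timestamp(start)
    times = t0 + pd.to_timedelta(np.arange(len(xy)) * interval_s, unit="s")
    return pd.DataFrame({"bird_id": "b1", "time": times, "lon": lon, "lat": lat})


def make_trip(colony, xy_km, bird_id="b1", interval_s=120, trip_index=1,
              start="2015-06-10T06:00:00Z"):
    """A Trip directly from planar offsets (all assumed outside the buffer)."""
    fixes = planar_track(colony, xy_km, start=start, interval_s=interval_s)
    fixes["bird_id"] = bird_id
    return cpf.Trip(bird_id=bird_id, trip_index=trip_index, fixes=fixes)
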