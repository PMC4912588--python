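"""Interpolation, trip segmentation, foraging filter and trip metrics."""

import math

import numpy as np
import pandas as pd
import pytest

import cpforage as cpf
from conftest import make_trip, planar_track


def oracle_haversine(lon1, lat1, lon2, lat2):
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    h = math.sin((p2 - p1) / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * cpf.EARTH_RADIUS_KM * math.asin(math.sqrt(h))


# ---------------------------------------------------------------- interpolate

class TestInterpolate:
    def test_two_fixes_120s_gives_13(self, colony):
        fixes = planar_track(colony, [(5, 0), (6, 0)], interval_s=120)
        out = cpf.interpolate(fixes, interval_s=10, colony=colony)
        assert len(out) == 13

    def test_linear_midpoint_half_km_east(self, colony):
        fixes = planar_track(colony, [(0, 0), (1, 0)], interval_s=100)
        out = cpf.interpolate(fixes, interval_s=10, colony=colony)
        mid = out.iloc[5]
        d = oracle_haversine(colony.lon, colony.lat, mid["lon"], mid["lat"])
        assert abs(d - 0.5) < 0.001  # within 1 m
        assert mid["lat"] == pytest.approx(colony.lat, abs=1e-5)

    def test_endpoints_preserved(self, colony):
        fixes = planar_track(colony, [(3, 4), (7, 1), (2, 9)], interval_s=95)
        out = cpf.interpolate(fixes, interval_s=10, colony=colony)
        for i in (0, -1):
            assert out["lon"].iloc[i] == pytest.approx(fixes["lon"].iloc[i], abs=1e-9)
            assert out["lat"].iloc[i] == pytest.approx(fixes["lat"].iloc[i], abs=1e-9)
        assert out["time"].iloc[-1] == fixes["time"].iloc[-1]

    def test_interpolated_path_never_longer(self, colony):
        """Chords cannot exceed the original polyline length."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(3, 12)
            xy = rng.uniform(-80, 80, size=(n, 2))
            fixes = planar_track(colony, xy, interval_s=int(rng.integers(60, 240)))
            out = cpf.interpolate(fixes, interval_s=10, colony=colony)
            l_orig = cpf.path_length_km(fixes["lon"], fixes["lat"])
            l_interp = cpf.path_length_km(out["lon"], out["lat"])
            assert l_interp <= l_orig + 1e-6

    def test_errors(self, colony):
        one = planar_track(colony, [(1, 1)])
        with pytest.raises(ValueError):
            cpf.interpolate(one, colony=colony)
        bad = planar_track(colony, [(1, 1), (2, 2), (3, 3)])
        bad.loc[2, "time"] = bad.loc[0, "time"]  # time goes backwards
        with pytest.raises(ValueError, match="non-monotone"):
            cpf.interpolate(bad, colony=colony)


# -------------------------------------------------------------- segment_trips

class TestSegmentTrips:
    def test_all_inside_no_trips(self, colony):
        fixes = planar_track(colony, [(0, 0)] * 5)
        assert cpf.segment_trips(fixes, colony) == []

    def test_two_excursions(self, colony):
        # inside, out 3 fixes, inside, out 2 fixes, inside
        xy = [(0, 0), (5, 0), (8, 0), (5, 0), (0, 0), (0, 6), (0, 9), (0, 0)]
        fixes = planar_track(colony, xy)
        trips = cpf.segment_trips(fixes, colony)
        assert [len(t) for t in trips] == [3, 2]
        assert [t.trip_index for t in trips] == [1, 2]
        assert all(t.complete for t in trips)
        assert trips[0].start_time == fixes["time"].iloc[1]
        assert trips[1].end_time == fixes["time"].iloc[6]

    def test_open_runs_flagged_incomplete(self, colony):
        xy = [(5, 0), (6, 0), (0, 0), (0, 7), (0, 8)]  # starts and ends at sea
        trips = cpf.segment_trips(planar_track(colony, xy), colony)
        assert [t.complete for t in trips] == [False, False]

    def test_roundtrip_with_simulator(self, small_dataset):
        """Segmentation recovers exactly the generated excursion count."""
        total = 0
        for _, bf in small_dataset.fixes.groupby("bird_id"):
            reg = cpf.interpolate(bf.reset_index(drop=True), 10,
                                  colony=small_dataset.colony)
            total += len(cpf.segment_trips(reg, small_dataset.colony))
        assert total == sum(small_dataset.n_excursions.values())

    def test_timeline_reconstruction(self, colony):
        """Trip fixes are exactly the outside fixes, in order, no overlap."""
        rng = np.random.default_rng(3)
        xy = rng.uniform(-0.5, 8, size=(60, 2))
        fixes = planar_track(colony, xy)
        d = cpf.haversine_km(fixes["lon"], fixes["lat"], colony.lon, colony.lat)
        outside = d > colony.buffer_m / 1000
        trips = cpf.segment_trips(fixes, colony)
        seg_times = pd.concat([t.fixes["time"] for t in trips]) if trips else pd.Series([], dtype="datetime64[ns, UTC]")
        assert list(seg_times) == list(fixes["time"][outside])


# ------------------------------------------------------------ filter_foraging

class TestFilterForaging:
    def test_strictly_over_40min(self, colony):
        def trip_of(minutes):
            return make_trip(colony, [(5 + i * 0.01, 0) for i in range(minutes + 1)],
                             interval_s=60)

        trips = [trip_of(30), trip_of(40), trip_of(41)]
        kept = cpf.filter_foraging(trips)
        assert len(kept) == 1
        assert kept[0].duration_min == pytest.approx(41)

    def test_empty(self):
        assert cpf.filter_foraging([]) == []

    def test_simulator_ground_truth(self, small_dataset, small_foraging_trips):
        """Exactly the loafing excursions are removed."""
        n_kept = sum(len(ts) for ts in small_foraging_trips.values())
        n_gen = sum(small_dataset.n_excursions.values())
        n_loaf = sum(small_dataset.n_loafing.values())
        assert n_kept == n_gen - n_loaf


# ------------------------------------------------------------------- metrics

class TestTripMetrics:
    def test_straight_out_and_back(self, colony):
        xy = [(i, 0) for i in range(1, 101)] + [(i, 0) for i in range(99, 0, -1)]
        m = cpf.compute_trip_metrics(make_trip(colony, xy), colony)
        assert m.max_distance_km == pytest.approx(100, rel=1e-4)
        assert m.length_km == pytest.approx(198, rel=1e-4)  # 1 km..100 km..1 km
        assert m.directness == pytest.approx(m.length_km / m.max_distance_km)

    def test_dogleg_directness(self, colony):
        # out 100 km north via a 50-km eastward dogleg (150 km path), straight back
        out = [(0, i) for i in range(1, 51)] + [(i, 50) for i in range(1, 51)] \
            + [(50 - i, 50 + i) for i in range(1, 51)]
        back_start = out[-1]
        m_out = len(out)
        back = [(back_start[0], back_start[1] - i) for i in range(1, 100)]
        trip = make_trip(colony, out + back)
        m = cpf.compute_trip_metrics(trip, colony)
        assert m.length_km >= m.max_distance_km
        # planar construction: 49 + 50 + 50*sqrt(2) + 99 km of path, 100 km range
        assert m.directness == pytest.approx((198 + 50 * np.sqrt(2)) / 100.0, rel=0.01)

    def test_against_bruteforce_oracle(self, colony):
        xy = [(3.2, 1.1), (7.5, -2.0), (12.3, 4.4), (9.9, 9.9), (4.0, 12.5), (1.0, 6.0)]
        trip = make_trip(colony, xy, interval_s=600)
        m = cpf.compute_trip_metrics(trip, colony)
        lon, lat = trip.fixes["lon"].to_numpy(), trip.fixes["lat"].to_numpy()
        length = sum(oracle_haversine(lon[i], lat[i], lon[i + 1], lat[i + 1])
                     for i in range(len(lon) - 1))
        maxd = max(oracle_haversine(colony.lon, colony.lat, lo, la) for lo, la in zip(lon, lat))
        assert m.length_km == pytest.approx(length, abs=1e-9)
        assert m.max_distance_km == pytest.approx(maxd, abs=1e-9)
        assert m.duration_h == pytest.approx(5 * 600 / 3600)
        assert m.directness == pytest.approx(length / maxd)

    def test_directness_lower_bound_on_simulated_trips(self, colony, small_foraging_trips):
        """Out-and-return geometry: directness >= 2(1 - buffer/maxdist)(1 - eps)."""
        eps = 0.02
        for trips in small_foraging_trips.values():
            for t in trips:
                m = cpf.compute_trip_metrics(t, colony)
                bound = 2.0 * (1.0 - colony.buffer_m / (1000.0 * m.max_distance_km)) * (1 - eps)
                assert m.directness >= bound

    def test_timezone_invariance(self, colony, tmp_path):
        """Metrics identical whether timestamps are written as Z or +02:00."""
        xy = [(0, 0), (10, 0), (20, 5), (10, 2), (0, 0)]
        base = planar_track(colony, xy, interval_s=1800)
        rows_z, rows_off = [], []
        for _, r in base.iterrows():
            t = r["time"]
            rows_z.append((r["bird_id"], t.strftime("%Y-%m-%dT%H:%M:%SZ"), r["lat"], r["lon"]))
            local = t.tz_convert("Etc/GMT-2")
            rows_off.append((r["bird_id"], local.isoformat(), r["lat"], r["lon"]))
        for name, rows in (("z.csv", rows_z), ("off.csv", rows_off)):
            pd.DataFrame(rows, columns=["bird_id", "timestamp", "lat", "lon"]).to_csv(
                tmp_path / name, index=False)
        fz = cpf.read_fixes(tmp_path / "z.csv")
        fo = cpf.read_fixes(tmp_path / "off.csv")
        pd.testing.assert_frame_equal(fz, fo)


# ------------------------------------------------------------------- summary

class TestSummarize:
    def test_closed_form(self):
        df = pd.DataFrame({"year": 2015, "duration_h": [10.0, 20.0, 30.0]})
        out = cpf.summarize_by_year(df)
        row = out[out["metric"] == "duration_h"].iloc[0]
        assert row["mean"] == pytest.approx(20.0)
        assert row["se"] == pytest.approx(5.7735, abs=1e-3)
        assert row["n"] == 3

    def test_single_trip(self):
        df = pd.DataFrame({"year": 2014, "duration_h": [7.0]})
        row = cpf.summarize_by_year(df).iloc[0]
        assert row["mean"] == 7.0
        assert np.isnan(row["se"])

    def test_farther_patches_increase_duration_and_range(self):
        """Pushing patches twice as far lengthens trips and max distance."""
        near = cpf.scenario_preset("high", "low", seed=9,
                                   patch_placement_range_km=(15.0, 30.0))
        far = cpf.scenario_preset("high", "low", seed=9,
                                  patch_placement_range_km=(30.0, 60.0))
        rows = []
        for year, sc in ((1, near), (2, far)):
            ds = cpf.simulate_population(sc, n_birds=5, trips_per_bird=3)
            for bird, bf in ds.fixes.groupby("bird_id"):
                reg = cpf.interpolate(bf.reset_index(drop=True), 30, colony=ds.colony)
                for t in cpf.filter_foraging(cpf.segment_trips(reg, ds.colony)):
                    m = cpf.compute_trip_metrics(t, ds.colony)
                    rows.append({"year": year, "duration_h": m.duration_h,
                                 "max_distance_km": m.max_distance_km})
        out = cpf.summarize_by_year(pd.DataFrame(rows))
        g = out.set_index(["year", "metric"])["mean"]
        assert g[(2, "duration_h")] > g[(1, "duration_h")]
        assert g[(2, "max_distance_km")] > g[(1, "max_distance_km")]
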