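"""Exposure of foraging trips to a proposed windfarm footprint.

Counts trips and birds with at least one fix inside a (synthetic) windfarm
polygon, the statistic used to assess interaction risk with offshore
development sites.
"""

import json

import cpforage as cpf

scenario = cpf.scenario_preset("low", "low", seed=11)
dataset = cpf.simulate_population(scenario, n_birds=8, trips_per_bird=4)
colony = dataset.colony

# synthetic footprint: a 15x15 km square 25 km east of the colony
proj = colony.projection
ring = []
for dx, dy in ((0, 0), (15, 0), (15, 15), (0, 15), (0, 0)):
    lon, lat = proj.inverse(25.0 + dx, -7.5 + dy)
    ring.append([float(lon), float(lat)])
feature_collection = {
    "type": "FeatureCollection",
    "features": [{"type": "Feature", "properties": {"name": "synthetic_windfarm"},
                  "geometry": {"type": "Polygon", "coordinates": [ring]}}],
}
with open("synthetic_windfarm.geojson", "w") as fh:
    json.dump(feature_collection, fh)
polygons = cpf.load_polygons("synthetic_windfarm.geojson")

trips = []
for bird, fixes in dataset.fixes.groupby("bird_id"):
    regular = cpf.interpolate(fixes.reset_index(drop=True), 10, colony=colony)
    trips.extend(cpf.filter_foraging(cpf.segment_trips(regular, colony)))

exposure = cpf.polygon_intersections(trips, polygons)
print(f"trips entering the footprint: {exposure.n_trips_hit} of "
      f"{exposure.n_trips_total} ({exposure.pct_trips}%)")
print(f"birds entering the footprint: {exposure.n_birds_hit} of "
      f"{exposure.n_birds_total} ({exposure.pct_birds}%)")
print("\nA bird counts as exposed if any of its trips has a fix inside any")
print("polygon; with incomplete population sampling these are lower bounds.")
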