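"""Gridded space use, core/home ranges and population-level extrapolation.

Builds per-bird time-in-area maps on the 5x5 km grid, extracts the 50%
core foraging area (CFA) and 95% home range (HRA), bootstraps the
area-vs-sample-size accumulation curve and fits the Michaelis-Menten model
y = a*x/(b+x) to predict the range of the whole (~10,000 bird) colony.
"""

import numpy as np

import cpforage as cpf

scenario = cpf.scenario_preset("low", "high", seed=42)
dataset = cpf.simulate_population(scenario, n_birds=10, trips_per_bird=4)
grid = cpf.GridSpec(colony=dataset.colony, cell_km=5.0)

bird_maps = []
for bird, fixes in dataset.fixes.groupby("bird_id"):
    regular = cpf.interpolate(fixes.reset_index(drop=True), 10, colony=dataset.colony)
    trips = cpf.filter_foraging(cpf.segment_trips(regular, dataset.colony))
    if trips:
        bird_maps.append(cpf.bird_time_map(trips, grid))

pooled = cpf.pool_maps(bird_maps)
for level, name in ((0.5, "CFA"), (0.95, "HRA")):
    rs = cpf.extract_range(pooled, level)
    print(f"pooled {name} ({level:.0%} of time): {len(rs.cells)} cells = {rs.area_km2:.0f} km^2")

rng = np.random.default_rng(1)
summary = cpf.representativeness_summary(bird_maps, level=0.5, n_boot=2000,
                                         rng=rng, population_n=10_000)
print(f"\nMichaelis-Menten fit: a = {summary.fit.a:.0f} km^2 (asymptotic CFA), "
      f"b = {summary.fit.b:.2f} birds (half-saturation)")
print(f"sample CFA {summary.sample_area_km2:.0f} km^2 vs "
      f"predicted population CFA {summary.predicted_population_area_km2:.0f} km^2")
print(f"proportion of population CFA sampled: {summary.prop_sampled:.2f}")
print(f"birds needed for 95% of the population CFA: {summary.n_for_95pct} (= 19*b)")
# A small b means birds are interchangeable; a large b means tracking a few
# individuals badly under-represents the colony's full foraging range.
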