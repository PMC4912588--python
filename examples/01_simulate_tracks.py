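"""Generate a synthetic GPS deployment and write it as a fix CSV.

Simulates 8 gannets making 4 excursions each under a low-resource,
high-patchiness prey scenario, then writes the fixes (plus the ground-truth
sidecar) the way a field campaign would deliver them.
"""

import cpforage as cpf

scenario = cpf.scenario_preset("low", "high", seed=42)
dataset = cpf.simulate_population(scenario, n_birds=8, trips_per_bird=4)

cpf.write_fixes_csv(dataset.fixes, "synthetic_fixes.csv")
cpf.write_truth_json(dataset, "synthetic_truth.json")

print(f"birds: {len(dataset.bird_ids)}")
print(f"fixes: {len(dataset.fixes)} at {scenario.fix_interval_s:.0f}-s interval")
print(f"excursions per bird: {dataset.n_excursions}")
print(f"loafing excursions: {sum(dataset.n_loafing.values())} "
      f"(these are < 40 min and will be filtered out downstream)")
print(f"prey patches: {len(dataset.patches)}, "
      f"{min(p.distance_km for p in dataset.patches):.0f}-"
      f"{max(p.distance_km for p in dataset.patches):.0f} km from the colony")
# The CSV (bird_id, timestamp, lat, lon) is exactly what read_fixes consumes.
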