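# cpforage

Analysis of central-place-forager GPS tracking data — built around the
question a colony-based tracking study has to answer before its maps can be
used for marine spatial planning: *how well does a handful of tracked birds
represent the space use of a colony of thousands, and how much does that
space use move between years?*

The package takes raw GPS fixes of seabirds (the motivating system is
northern gannets *Morus bassanus* breeding on a small colony, tracked with
2-min GPS loggers during chick rearing) and produces:

1. **Foraging trips** — tracks are interpolated to a regular 10-s step,
   cut into excursions at a 30-m colony buffer, and excursions of 40 min or
   less (loafing near the colony) are discarded. Each trip gets duration
   (h), path length (km), maximum distance from the colony (km) and
   *directness* = length / max distance (2 = straight out-and-back).
2. **Time-in-area ranges** — the proportion of each bird's at-sea time per
   5×5 km grid cell; cells ranked by time, the smallest top-ranked set
   holding 50% of time is the core foraging area (CFA) and 95% the home
   range area (HRA).
3. **Representativeness** — the mean range area of random subsets of
   1..N tracked birds (bootstrap), fitted to the Michaelis–Menten model

   y = a·x / (b + x)

   where *a* is the asymptotic range area of the whole population and *b*
   the number of birds needed to cover half of it (an inter-individual
   variation index). The same machinery on one bird's trips gives an
   intra-individual consistency index.
4. **Overlap statistics** — directional between-year overlap of range
   cells, corrected for incomplete sampling by
   `population overlap = O × 100 / S` (O = sample overlap %, S = the second
   year's sampled proportion of its predicted population range, %);
   per-cell bird/year usage counts; and counts of trips and birds entering
   external polygon footprints (e.g. proposed windfarms, as GeoJSON).
5. **Synthetic tracks** — a seeded central-place-forager movement model
   (commute / area-restricted-search, prey patches under four
   resource × patchiness scenarios) that generates realistic multi-bird
   deployments with known ground truth, used to validate every stage.

## Worked example

```python
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
print(cpf.extract_range(pooled, 0.5).area_km2)   # pooled CFA, km^2

summary = cpf.representativeness_summary(
    bird_maps, level=0.5, n_boot=2000, rng=np.random.default_rng(1))
print(summary.fit.a, summary.fit.b, summary.prop_sampled)
```

prints (for this seed):

```
250.0
272.3952978449995 0.6733701644686163 0.9178456318154883
```

— the 10 tracked birds' pooled CFA is 250 km², the fitted asymptote
predicts a 272 km² CFA for an arbitrarily large sample, so this sample
already covers 92% of the population-level core area; b ≈ 0.7 birds means
individuals here are highly interchangeable (the scenario packs prey into
a few tight patches that every bird shares). The `examples/` directory
holds one short script per capability (simulation, trip metrics, ranges +
representativeness, between-year overlap, windfarm exposure), each printing
and explaining its numbers.

A thin CLI covers the shell-level workflow:

```sh
cpforage simulate-tracks --resource low --patchiness high --seed 1 --out fixes.csv
cpforage run-year fixes.csv --year 2015 --outdir out/ --seed 1
cpforage compare-years y14.csv y15.csv --years 2014,2015 --out overlaps.csv --seed 1
```

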