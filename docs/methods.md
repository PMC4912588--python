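# Methods

This note documents the models, parameter choices and numerical rules
behind `cpforage`, and what the synthetic-data validation does and does not
demonstrate.

## Track regularisation and trip definition

Raw deployments log a position nominally every 2 min, with gaps from diving
and missed satellite locks. Each bird's series is linearly interpolated to a
regular 10-s step in a colony-centred azimuthal-equidistant plane (spherical
model, R = 6371.0088 km), then converted back to lon/lat. The planar frame
is used because linear interpolation in raw lon/lat distorts east-west
distances at high latitude; azimuthal-equidistant is chosen because it
preserves radial distance from the colony exactly, which is the quantity the
trip definition and the maximum-range metric depend on. Every gap is
interpolated; gaps longer than 30 min (configurable) are logged as a QC
warning rather than split, since splitting rules would themselves need
justification. The first and last original fixes are always retained, so an
interval that does not divide the series span exactly produces one shorter
terminal step.

A trip is a maximal run of consecutive fixes strictly farther than a 30-m
buffer from the colony point; the trip spans its first through last outside
fix. Runs open at either end of the series (departure or return not
recorded) are flagged incomplete and excluded from metrics and space use by
default, to avoid biased durations. Trips of 40 min or less are discarded as
loafing; "over 40 min" is implemented as strictly greater.

Trip metrics: duration between boundary fixes (h); path length as the sum
of great-circle distances between consecutive fixes (km); maximum
great-circle distance from the colony (km); directness = length / maximum
distance (dimensionless, 2 for a straight out-and-back, undefined and
reported missing if the maximum distance is zero). Great-circle (haversine)
distance is the default everywhere because it is reproducible without a
projection choice; at the ≤ 200 km scales involved the difference from the
projected-plane distance is below 10⁻⁴ relative.

Yearly summaries are plain per-year means ± standard errors over trips.
Mixed-model adjusted means are deliberately out of scope: they belong to
inference about year effects, not to the pipeline's descriptive output.

## Time-in-area ranges

Space use is measured as time per cell on a square 5×5 km grid in the
colony-centred plane, with the colony at a cell corner (a deterministic
anchor; the published grid's alignment is unknowable, so no result here
should be read as cell-exact). Each 10-s interval is assigned to the cell
containing its fix; a bird's map is per-cell seconds divided by its total
at-sea seconds, using foraging-trip fixes only (colony and loafing time are
not at-sea distribution). The pooled map is the unweighted mean of per-bird
proportion maps, so a bird with many trips does not dominate; it sums to 1
by construction.

A range at level q is the smallest set of top-ranked cells whose cumulative
proportion reaches q (q = 0.50: core foraging area, CFA; q = 0.95: home
range area, HRA). The cell at which the cumulative sum first crosses q is
included, so coverage is always ≥ q; ties in weight are broken by ascending
(row, col) index for determinism; the comparison uses a 10⁻⁹ tolerance so
exact ties with the level are not lost to floating point. Area is
cell-area × cell count. Greedy ranking provably gives the minimum-cardinality
set, which the tests confirm against exhaustive subset enumeration.

## Representativeness: accumulation curves and the Michaelis–Menten model

For n = 1..N tracked birds, draw n distinct birds uniformly (without
replacement within a draw, independently across draws; a draw represents
"having tracked n birds"), pool their maps, extract the range, and average
the area over `n_boot` draws (default 10,000). Draws are generated as the
first n entries of a random permutation (argsort of iid uniforms), which is
vectorised and exactly reproducible from the seed. The mean-area points are
fitted by least squares to

  y = a·x / (b + x)

with positivity bounds, initialised at a₀ = max y and b₀ = the x whose y is
nearest a₀/2, relative tolerance 10⁻¹⁰, at most 10,000 function evaluations;
non-convergence raises with diagnostics rather than clipping. The curve is
fitted to the bootstrap means (one point per n), not to all replicates.
Derived quantities: predicted population-level area a·N/(b+N) (default
N = 10,000 birds, configurable); sampled proportion = sampled range area /
predicted population area; and the closed-form sample size for a fraction f
of the asymptote, x = f·b/(1−f) (19·b for f = 0.95), rounded to the nearest
integer.

The same accumulation applied to one bird's trips gives the intra-individual
consistency index (fitted b = trips needed to cover half the bird's range).
Within a bird, subsets of trips are pooled by tallying seconds across the
chosen trips (a trip is not an exchangeable sampling unit of equal weight
the way a bird is; the bird's map restricted to a trip subsample is its
time-proportion over those trips). Birds with fewer than three foraging
trips are skipped with a logged reason.

Parameter recovery: on synthetic noisy curves at the study's scale
(a ≈ 6000 km², b ≈ 15, point noise sd 100 km², n ≤ 15) the estimator is
unbiased — the median fitted a and b over 200 curves land within ~1% of
truth — but individual fits scatter: the median per-curve |relative error|
is ≈ 5% for a and ≈ 9% for b, because the half-saturation sits at the edge
of the design and the two parameters are strongly correlated there. Single
fitted values of b from ≤ 15 birds should therefore be read as indices, not
precise estimates.

## Overlap statistics

Directional sample overlap O(X→Y) = 100·|X∩Y| / |X| over range cell sets on
a common grid. The population correction divides by the *second* year's
sampled proportion S (in %): population overlap = O × 100 / S. This is the
direction convention whose arithmetic is self-consistent with the
representativeness table (e.g. O = 32, S = 61 → 52); it assumes detection is
equally likely in overlapping and non-overlapping cells, and values slightly
above 100% can arise from extrapolation slack and are reported as computed.
Per-cell usage counts (how many birds within a year, or years across the
study, use each cell) are simple tallies with a histogram summary.

Polygon exposure: a trip intersects a footprint if at least one fix lies
strictly inside any polygon (point-in-polygon in lon/lat via shapely); a
bird intersects if any of its trips does; percentages are rounded to
integers. At a 10-s fix interval a trip can only cross a footprint
"between fixes" if it traverses it in under 10 s, so fix-in-polygon is the
operative definition; a refinement option re-interpolates tracks to a finer
step (e.g. 1 s) for edge-on geometries. Invalid (self-intersecting)
polygons are rejected by feature name.

## Synthetic track generator

The generator exists to validate the pipeline against known ground truth
and to encode the four prey-scenario contrasts (resource level ×
patchiness) as *orderings*, not calibrated magnitudes — no quantitative
prey model is available to calibrate against.

Prey is a set of circular patches in an annulus 20–60 km from the colony
(radius ≈ 6 km, gamma-distributed weights). High patchiness packs patches
into 2 tight clusters (sd 4 km, clamped back into the annulus so no patch
sits on the colony); low patchiness disperses centres uniformly. Low
resource halves patch weights, and the scenario presets give low-resource
runs fewer patches (5 vs 10) and generalist birds (specialisation 0.2 vs
0.9): with scarce prey every bird works the same few patches and moves
between patches within a trip (1 + Poisson(1.5) patch visits vs
1 + Poisson(0.2)). Bird preferences are Dirichlet draws around the patch
weights whose concentration shrinks with specialisation; specialisation 1
is a strict one-hot specialist.

Movement: outbound biased correlated random walk toward a weight-sampled
patch at 45 km/h (von Mises heading noise, κ = 12); area-restricted search
inside the patch at 10 km/h with wide turns (κ = 0.5), reflected back when
leaving the patch; dwell time scales with patch weight (base 1.5 h, floored
at 0.6 h so every foraging trip safely exceeds the 40-min loafing
threshold); then a return leg. Speeds are plausible for a large plunge-diving
seabird and configurable. Fixes are emitted every 120 s; loafing excursions
(default 15% of excursions) wander within 2 km of the colony for under
40 min; interior at-sea fixes are dropped at 2% to exercise interpolation
(never excursion boundaries, so the generated excursion count is exactly
recoverable by segmentation — a tested round-trip invariant). Per-bird trip
counts can be an exact integer or a ≥ 1-truncated Poisson with a given mean,
matching the unequal effort of real deployments (means ~2–6 trips/bird).
Everything is driven by one numpy Generator, so a seed reproduces the fix
table bitwise.

What the simulator does *not* emulate: diving and energetics, wind and
current drift, vessel attraction, memory across trips beyond the fixed
preference weights, and location error on fixes. Passing tests therefore show
the pipeline's logic and statistics are correct on data with known
structure — not that the movement model is a faithful gannet.

## Problem sizes and determinism

Validation runs use deliberately small configurations (6–15 birds, 3–6
excursions each, bootstrap 150–2,000 draws, scenario contrasts averaged
over 20 seeded replicates), chosen so the full suite exercises every stage,
including four-scenario contrasts and a byte-identical determinism check of
the end-to-end pipeline, at desk scale. Production-scale defaults
(n_boot = 10,000, N = 10,000 birds) are the package defaults. All
randomness flows through explicitly passed numpy Generators; rerunning any
stage with the same seed and config reproduces outputs byte-for-byte.

## Known limitations

- The published study's per-year field results (areas, trip-metric means,
  cell counts) are not reproducible without its tracking data and grid;
  only its worked-example arithmetic is (see `scripts/acceptance.py`).
- The grid anchor is a convention; absolute cell identities are not
  comparable across different colony coordinates or cell sizes.
- The sample-incompleteness correction inherits the equal-detection
  assumption; overlaps above 100% are a visible symptom of its
  approximate nature.
- Interpolation across very long gaps fabricates straight-line movement;
  the QC warning is the only guard.
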