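"""Synthetic central-place-forager GPS tracks.

Generates multi-bird, multi-trip fix series that look like raw seabird
tracking data (nominal 2-min interval, loafing excursions, occasional
dropped fixes) from an explicit movement model:

* prey is a set of circular patches around the colony, placed under one of
  four scenarios crossing resource level (low/high) with patchiness
  (high = patches packed into a few tight clusters, low = patches dispersed
  over the placement annulus);
* each bird holds its own patch-preference weights, drawn with a
  configurable specialisation level — specialists concentrate on one patch,
  generalists share the population-wide weights;
* a trip is an outbound biased correlated random walk to a weight-sampled
  patch at commute speed, area-restricted search (slow, tortuous) inside the
  patch with dwell time scaled by patch weight, possible onward moves to
  further patches when resources are low, and a return leg to the colony.

The quadrant logic the scenarios encode: dispersed prey (low patchiness)
gives large pooled foraging areas; scarce prey (low resource) forces birds
over the same few patches, giving high inter-individual overlap.

Simulation runs in the colony-centred planar frame (km) and is converted to
lon/lat on output, so downstream code consumes it exactly like field data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .represent import AccumulationCurve
from .trips import ColonySpec

#: Les Etacs gannetry (Alderney, Channel Islands) with a 30 m buffer —
#: the default colony for synthetic data.
DEFAULT_COLONY = ColonySpec(lon=-2.239, lat=49.705, buffer_m=30.0)

_MAX_TRIP_STEPS = 20_000


@dataclass(frozen=True)
class PreyPatch:
    """A circular prey patch: planar offset from the colony (km east/north),
    radius (km) and a relative attractiveness weight."""

    x_km: float
    y_km: float
    radius_km: float
    weight: float

    def __post_init__(self):
        if self.radius_km <= 0 or self.weight <= 0:
            raise ValueError("patch radius and weight must be positive")

    @property
    def distance_km(self) -> float:
        return float(np.hypot(self.x_km, self.y_km))


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one prey-distribution scenario.

    ``bird_specialization`` in [0, 1]: 0 means every bird shares the
    population-wide patch weights, 1 means each bird is a single-patch
    specialist. ``loafing_trip_rate`` is the probability that a generated
    excursion is a short (< 40 min) loaf near the colony.
    """

    resource_level: str  # "low" | "high"
    patchiness: str  # "high" | "low"
    n_patches: int = 8
    patch_radius_km: float = 6.0
    patch_placement_range_km: tuple[float, float] = (20.0, 60.0)
    bird_specialization: float = 0.5
    commute_speed_kmh: float = 45.0
    ars_speed_kmh: float = 10.0
    fix_interval_s: float = 120.0
    loafing_trip_rate: float = 0.15
    drop_fix_rate: float = 0.02
    n_clusters: int = 2  # tight clusters used when patchiness == "high"
    cluster_sd_km: float = 4.0
    dwell_base_h: float = 1.5
    seed: int | None = None

    def __post_init__(self):
        if self.resource_level not in ("low", "high"):
            raise ValueError("resource_level must be 'low' or 'high'")
        if self.patchiness not in ("low", "high"):
            raise ValueError("patchiness must be 'low' or 'high'")
        if self.n_patches < 1:
            raise ValueError("n_patches must be >= 1")
        if self.commute_speed_kmh <= 0 or self.ars_speed_kmh <= 0:
            raise ValueError("speeds must be positive")
        if self.fix_interval_s <= 0:
            raise ValueError("fix_interval_s must be positive")
        if not (0.0 <= self.bird_specialization <= 1.0):
            raise ValueError("bird_specialization must be in [0, 1]")
        if not (0.0 <= self.loafing_trip_rate < 1.0):
            raise ValueError("loafing_trip_rate must be in [0, 1)")
        rmin, rmax = self.patch_placement_range_km
        if not (0 < rmin <= rmax):
            raise ValueError("patch_placement_range_km must satisfy 0 < min <= max")


def scenario_preset(resource_level: str, patchiness: str, seed: int | None = None,
                    **overrides) -> ScenarioConfig:
    """The four study scenarios with quadrant-consistent defaults.

    Low resource: fewer, lighter patches, generalist birds that move between
    patches within a trip (everyone searches everywhere). High resource:
    more, richer patches and specialist birds.
    """
    params = dict(
        resource_level=resource_level,
        patchiness=patchiness,
        n_patches=5 if resource_level == "low" else 10,
        bird_specialization=0.2 if resource_level == "low" else 0.9,
        seed=seed,
    )
    params.update(overrides)
    return ScenarioConfig(**params)


@dataclass
class SimulatedDataset:
    """Synthetic fixes plus the ground truth that generated them."""

    fixes: pd.DataFrame = field(repr=False)
    colony: ColonySpec = DEFAULT_COLONY
    scenario: ScenarioConfig = None
    patches: list[PreyPatch] = field(default_factory=list)
    bird_weights: dict[str, np.ndarray] = field(default_factory=dict)
    n_excursions: dict[str, int] = field(default_factory=dict)
    n_loafing: dict[str, int] = field(default_factory=dict)

    @property
    def bird_ids(self) -> list[str]:
        return sorted(self.fixes["bird_id"].unique())


def place_patches(scenario: ScenarioConfig, rng: np.random.Generator) -> list[PreyPatch]:
    """Draw patch locations and weights for a scenario.

    High patchiness packs the patches into ``n_clusters`` tight clusters
    (small total footprint); low patchiness disperses centres uniformly over
    the placement annulus. Resource level scales patch weights (lighter
    patches under low resource mean shorter dwells and longer searches).
    """
    n = scenario.n_patches
    rmin, rmax = scenario.patch_placement_range_km
    centers = np.empty((n, 2))
    if scenario.patchiness == "high":
        k = min(scenario.n_clusters, n)
        ang = rng.uniform(0, 2 * np.pi, size=k)
        rad = rng.uniform(rmin, rmax, size=k)
        cl = np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=1)
        assign = rng.integers(0, k, size=n)
        centers = cl[assign] + rng.normal(0.0, scenario.cluster_sd_km, size=(n, 2))
        # keep scattered centres inside the placement annulus so no patch
        # ends up on top of the colony
        r = np.hypot(centers[:, 0], centers[:, 1])
        scale = np.clip(r, rmin, rmax) / np.maximum(r, 1e-9)
        centers = centers * scale[:, None]
    else:
        ang = rng.uniform(0, 2 * np.pi, size=n)
        rad = rng.uniform(rmin, rmax, size=n)
        centers = np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=1)
    weight_scale = 0.5 if scenario.resource_level == "low" else 1.5
    weights = rng.gamma(3.0, 1.0, size=n) * weight_scale
    radii = scenario.patch_radius_km * rng.uniform(0.7, 1.3, size=n)
    return [
        PreyPatch(x_km=float(cx), y_km=float(cy), radius_km=float(r), weight=float(w))
        for (cx, cy), r, w in zip(centers, radii, weights)
    ]


def draw_bird_weights(patches: list[PreyPatch], specialization: float,
                      rng: np.random.Generator) -> np.ndarray:
    """One bird's patch-preference weights (sum to 1).

    Dirichlet around the population prior; concentration shrinks with
    specialisation. At specialisation 1 the bird is a strict single-patch
    specialist (one-hot, patch sampled by prior weight).
    """
    prior = np.array([p.weight for p in patches], dtype=float)
    prior = prior / prior.sum()
    if specialization >= 1.0:
        w = np.zeros(len(patches))
        w[rng.choice(len(patches), p=prior)] = 1.0
        return w
    conc = 10.0 ** (2.0 - 3.0 * specialization) * len(patches)
    return rng.dirichlet(np.maximum(prior * conc, 1e-3))


def _loafing_planar(scenario: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Outside-buffer fixes of a short loaf within 2 km of the colony."""
    dt_h = scenario.fix_interval_s / 3600.0
    # keep the whole excursion, colony fix to colony fix, strictly under 40 min
    duration_min = rng.uniform(8.0, 34.0)
    n_steps = max(2, int(duration_min * 60.0 / scenario.fix_interval_s) - 1)
    heading = rng.uniform(0, 2 * np.pi)
    x, y = 0.3 * np.cos(heading), 0.3 * np.sin(heading)
    pts = [(x, y)]
    for _ in range(n_steps - 1):
        heading += rng.vonmises(0.0, 4.0)
        speed = rng.uniform(0.5, 3.5)  # drifting/loafing, km/h
        x += speed * dt_h * np.cos(heading)
        y += speed * dt_h * np.sin(heading)
        r = float(np.hypot(x, y))
        if r > 1.8:  # stay adjacent to the colony
            x, y = x * 1.6 / r, y * 1.6 / r
        elif r < 0.15:  # and clear of the buffer
            s = 0.25 / max(r, 1e-9)
            x, y = x * s, y * s
        pts.append((x, y))
    return np.asarray(pts)


def _commute(pts, x, y, tx, ty, arrive_km, speed_kmh, dt_h, rng):
    """Biased correlated random walk from (x, y) to within ``arrive_km`` of
    the target; appends fixes to ``pts`` and returns the final position."""
    while np.hypot(tx - x, ty - y) > arrive_km and len(pts) < _MAX_TRIP_STEPS:
        bearing = np.arctan2(ty - y, tx - x)
        heading = bearing + rng.vonmises(0.0, 12.0)
        step = speed_kmh * dt_h * max(0.2, rng.normal(1.0, 0.05))
        step = min(step, float(np.hypot(tx - x, ty - y)) + 0.3 * arrive_km)
        x += step * np.cos(heading)
        y += step * np.sin(heading)
        pts.append((x, y))
    return x, y


def _forage_planar(patches, bird_weights, scenario, rng) -> np.ndarray:
    """Outside-buffer fixes of one foraging trip."""
    dt_h = scenario.fix_interval_s / 3600.0
    n_patches = len(patches)
    lam = 1.5 if scenario.resource_level == "low" else 0.2
    n_visits = 1 + int(rng.poisson(lam))
    n_visits = min(n_visits, n_patches)
    mean_w = float(np.mean([p.weight for p in patches]))

    pts: list[tuple[float, float]] = []
    x = y = 0.0
    current = None
    for _ in range(n_visits):
        probs = np.asarray(bird_weights, dtype=float).copy()
        if current is not None:
            probs[current] = 0.0
        if probs.sum() <= 0:
            break  # strict specialist has nowhere else to go
        probs = probs / probs.sum()
        current = int(rng.choice(n_patches, p=probs))
        patch = patches[current]
        x, y = _commute(pts, x, y, patch.x_km, patch.y_km, patch.radius_km,
                        scenario.commute_speed_kmh, dt_h, rng)
        # area-restricted search: slow, high turn variance, dwell ~ weight
        # floor keeps even the lightest-patch foraging trip well past the
        # 40-min loafing threshold
        dwell_h = float(np.clip(
            scenario.dwell_base_h * (patch.weight / mean_w) * rng.lognormal(0.0, 0.3),
            0.6, 8.0))
        heading = rng.uniform(0, 2 * np.pi)
        for _ in range(max(1, int(dwell_h / dt_h))):
            if len(pts) >= _MAX_TRIP_STEPS:
                break
            heading += rng.vonmises(0.0, 0.5)
            step = scenario.ars_speed_kmh * dt_h * rng.uniform(0.5, 1.5)
            nx, ny = x + step * np.cos(heading), y + step * np.sin(heading)
            if np.hypot(nx - patch.x_km, ny - patch.y_km) > patch.radius_km:
                heading = np.arctan2(patch.y_km - y, patch.x_km - x) + rng.vonmises(0.0, 4.0)
                nx, ny = x + step * np.cos(heading), y + step * np.sin(heading)
            x, y = nx, ny
            pts.append((x, y))
    # inbound leg
    _commute(pts, x, y, 0.0, 0.0, scenario.commute_speed_kmh * dt_h,
             scenario.commute_speed_kmh, dt_h, rng)
    return np.asarray(pts)


def _excursion_planar(patches, bird_weights, scenario, rng, loafing: bool) -> np.ndarray:
    if loafing:
        return _loafing_planar(scenario, rng)
    return _forage_planar(patches, bird_weights, scenario, rng)


def simulate_bird_trip(
    patches: list[PreyPatch],
    bird_weights,
    colony: ColonySpec,
    scenario: ScenarioConfig,
    rng: np.random.Generator,
    bird_id: str = "bird_01",
    start_time="2015-06-01T06:00:00Z",
    loafing: bool | None = None,
) -> pd.DataFrame:
    """One excursion as a fix series (colony fix, at-sea fixes, colony fix).

    ``loafing=None`` draws the loafing branch with the scenario's rate.
    """
    if not patches:
        raise ValueError("need at least one patch")
    w = np.asarray(bird_weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("bird weights must have positive sum")
    if loafing is None:
        loafing = bool(rng.random() < scenario.loafing_trip_rate)
    sea = _excursion_planar(patches, w / w.sum(), scenario, rng, loafing)
    xy = np.vstack([[0.0, 0.0], sea, [0.0, 0.0]])
    proj = colony.projection
    lon, lat = proj.inverse(xy[:, 0], xy[:, 1])
    t0 = pd.Timestamp(start_time)
    times = t0 + pd.to_timedelta(np.arange(len(xy)) * scenario.fix_interval_s, unit="s")
    return pd.DataFrame({"bird_id": bird_id, "time": times, "lon": lon, "lat": lat})


def _trips_for_bird(trips_per_bird, rng) -> int:
    """Exact count if int; otherwise Poisson truncated at >= 1 with that mean."""
    if isinstance(trips_per_bird, (int, np.integer)):
        if trips_per_bird < 1:
            raise ValueError("trips_per_bird must be >= 1")
        return int(trips_per_bird)
    mean = float(trips_per_bird)
    while True:
        k = int(rng.poisson(mean))
        if k >= 1:
            return k


def simulate_population(
    scenario: ScenarioConfig,
    n_birds: int,
    trips_per_bird=6,
    rng: np.random.Generator | None = None,
    colony: ColonySpec = DEFAULT_COLONY,
    start_time="2015-06-01T00:00:00Z",
) -> SimulatedDataset:
    """Full synthetic deployment: ``n_birds`` birds, each with its own patch
    preferences, interleaving colony rests and excursions.

    ``trips_per_bird`` may be an exact integer count (loafing excursions
    included) or a float mean of a >= 1-truncated Poisson. Interior at-sea
    fixes are dropped at the scenario's ``drop_fix_rate`` to emulate missed
    GPS locks (excursion boundaries are never dropped).
    """
    if n_birds < 1:
        raise ValueError("n_birds must be >= 1")
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    patches = place_patches(scenario, rng)
    dt = scenario.fix_interval_s
    t0 = pd.Timestamp(start_time)
    proj = colony.projection

    frames = []
    bird_weights: dict[str, np.ndarray] = {}
    n_exc: dict[str, int] = {}
    n_loaf: dict[str, int] = {}
    for i in range(n_birds):
        bird = f"bird_{i + 1:02d}"
        w = draw_bird_weights(patches, scenario.bird_specialization, rng)
        bird_weights[bird] = w
        k = _trips_for_bird(trips_per_bird, rng)
        n_exc[bird] = k
        n_loaf[bird] = 0
        xy_blocks: list[np.ndarray] = []
        keep_blocks: list[np.ndarray] = []
        for _ in range(k):
            rest = int(rng.integers(2, 6))
            xy_blocks.append(np.zeros((rest, 2)))
            keep_blocks.append(np.ones(rest, dtype=bool))
            loafing = bool(rng.random() < scenario.loafing_trip_rate)
            n_loaf[bird] += int(loafing)
            sea = _excursion_planar(patches, w, scenario, rng, loafing)
            keep = np.ones(len(sea), dtype=bool)
            if scenario.drop_fix_rate > 0 and len(sea) > 2:
                keep[1:-1] = rng.random(len(sea) - 2) >= scenario.drop_fix_rate
            xy_blocks.append(sea)
            keep_blocks.append(keep)
        xy_blocks.append(np.zeros((2, 2)))
        keep_blocks.append(np.ones(2, dtype=bool))
        xy = np.vstack(xy_blocks)
        keep = np.concatenate(keep_blocks)
        times = t0 + pd.to_timedelta(np.arange(len(xy)) * dt, unit="s")
        lon, lat = proj.inverse(xy[:, 0], xy[:, 1])
        frames.append(pd.DataFrame(
            {"bird_id": bird, "time": times[keep], "lon": lon[keep], "lat": lat[keep]}
        ))
    fixes = pd.concat(frames, ignore_index=True)
    return SimulatedDataset(
        fixes=fixes, colony=colony, scenario=scenario, patches=patches,
        bird_weights=bird_weights, n_excursions=n_exc, n_loafing=n_loaf,
    )


def simulate_accumulation(
    a: float, b: float, noise_sd: float, n_max: int,
    rng: np.random.Generator | None = None,
) -> AccumulationCurve:
    """Synthetic Michaelis-Menten accumulation curve with Gaussian noise
    (truncated at 0) — a recovery-test harness for ``fit_mm``."""
    if a <= 0 or b <= 0:
        raise ValueError("a and b must be positive")
    if n_max < 3:
        raise ValueError("n_max must be >= 3")
    rng = np.random.default_rng() if rng is None else rng
    n = np.arange(1, n_max + 1, dtype=float)
    y = a * n / (b + n)
    if noise_sd > 0:
        y = np.maximum(y + rng.normal(0.0, noise_sd, size=n_max), 0.0)
    return AccumulationCurve(unit="individuals", n=n.astype(int), mean_area_km2=y,
                             n_boot=0, level=float("nan"))


def write_fixes_csv(fixes: pd.DataFrame, path) -> None:
    """GPS fix CSV (bird_id, ISO-8601 UTC timestamp, lat, lon) in the same
    dialect the pipeline reader consumes."""
    out = pd.DataFrame({
        "bird_id": fixes["bird_id"],
        "timestamp": fixes["time"].dt.strftime("%Y-%m-%dT%H:%M:%SZ"),
        "lat": fixes["lat"].map(lambda v: f"{v:.7f}"),
        "lon": fixes["lon"].map(lambda v: f"{v:.7f}"),
    })
    out.to_csv(path, index=False)


def write_truth_json(dataset: SimulatedDataset, path) -> None:
    """Ground-truth sidecar: scenario, patches, per-bird weights, effort."""
    truth = {
        "scenario": asdict(dataset.scenario),
        "colony": asdict(dataset.colony),
        "patches": [asdict(p) for p in dataset.patches],
        "bird_weights": {b: list(map(float, w)) for b, w in dataset.bird_weights.items()},
        "n_excursions": dataset.n_excursions,
        "n_loafing": dataset.n_loafing,
    }
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
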