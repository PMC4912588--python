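"""Sample-size accumulation curves, Michaelis-Menten fits and
population-level range predictions.

A tracked sample rarely covers the whole colony's range. To quantify how
much is missing, the range area is computed for random subsets of 1..N
tracked birds (bootstrapped), giving a mean area-vs-sample-size curve which
is fitted to the saturating Michaelis-Menten form

    y = a * x / (b + x)

where ``a`` is the asymptotic (population-level) range area and ``b`` the
number of individuals at which half of it is reached — an index of
inter-individual variation. The same machinery applied to one bird's trips
yields an intra-individual consistency index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .spaceuse import _LEVEL_EPS, Cell, TimeInAreaMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AccumulationCurve:
    """Mean range area versus number of sampled units (birds or trips)."""

    unit: str  # "individuals" | "trips"
    n: np.ndarray  # 1..N, no gaps
    mean_area_km2: np.ndarray
    n_boot: int
    level: float


@dataclass(frozen=True)
class MMFit:
    """Michaelis-Menten parameters: asymptote ``a`` (km^2), half-saturation
    ``b`` (sample size)."""

    a: float
    b: float

    def predict(self, x):
        return self.a * np.asarray(x, dtype=float) / (self.b + np.asarray(x, dtype=float))


class FitError(RuntimeError):
    """Nonlinear fit failed; message carries the optimiser diagnostics."""


@dataclass(frozen=True)
class RepresentativenessSummary:
    """How well the tracked sample represents the population-level range."""

    level: float
    n_birds: int
    fit: MMFit
    sample_area_km2: float
    population_n: int
    predicted_population_area_km2: float
    prop_sampled: float
    n_for_95pct: int


@dataclass(frozen=True)
class IndividualConsistency:
    bird_id: str
    n_trips: int
    fit: MMFit
    curve: AccumulationCurve

    @property
    def trips_for_half_area(self) -> float:
        return self.fit.b


def _maps_to_matrix(maps: list[TimeInAreaMap]) -> tuple[np.ndarray, list[Cell], float]:
    """Stack per-bird weight dicts into a dense (birds x cells) matrix."""
    cells = sorted({c for m in maps for c in m.weights})
    index = {c: j for j, c in enumerate(cells)}
    M = np.zeros((len(maps), len(cells)))
    for i, m in enumerate(maps):
        for cell, w in m.weights.items():
            M[i, index[cell]] = w
    cell_km = next((m.grid.cell_km for m in maps if m.grid is not None), 5.0)
    return M, cells, cell_km


def _range_cell_counts(pooled: np.ndarray, level: float) -> np.ndarray:
    """Number of top-ranked cells holding >= level, per row of ``pooled``.

    Rows are proportion vectors summing to 1; only the count (hence area) is
    needed, so ties in weight do not matter here.
    """
    ranked = -np.sort(-pooled, axis=-1)
    cum = np.cumsum(ranked, axis=-1)
    return 1 + np.argmax(cum >= level - _LEVEL_EPS, axis=-1)


def accumulation_curve(
    maps: list[TimeInAreaMap],
    level: float,
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
    unit: str = "individuals",
) -> AccumulationCurve:
    """Bootstrap mean range area for 1..N randomly sampled birds.

    Each bootstrap draw picks ``n`` distinct birds (without replacement
    within a draw, independently across draws), pools their maps with equal
    weight and measures the area of the ``level`` range; the curve point is
    the mean over ``n_boot`` draws.
    """
    if len(maps) < 2:
        raise ValueError("accumulation needs at least 2 birds")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    M, _, cell_km = _maps_to_matrix(maps)
    N = M.shape[0]
    means = np.empty(N)
    for n in range(1, N + 1):
        # n distinct birds per draw: first n slots of a random permutation
        order = np.argsort(rng.random((n_boot, N)), axis=1)[:, :n]
        pooled = M[order].mean(axis=1)
        counts = _range_cell_counts(pooled, level)
        means[n - 1] = counts.mean() * cell_km ** 2
    return AccumulationCurve(unit=unit, n=np.arange(1, N + 1), mean_area_km2=means,
                             n_boot=n_boot, level=level)


def fit_mm(curve: AccumulationCurve, xtol: float = 1e-10, max_iter: int = 10_000) -> MMFit:
    """Least-squares Michaelis-Menten fit to an accumulation curve.

    Initialised at a0 = max(y), b0 = the x whose y is closest to a0/2, with
    positivity bounds on both parameters.
    """
    x = np.asarray(curve.n, dtype=float)
    y = np.asarray(curve.mean_area_km2, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("fit needs at least 3 distinct sample sizes")
    a0 = float(y.max())
    b0 = float(x[np.argmin(np.abs(y - a0 / 2.0))])
    b0 = max(b0, 1e-6)
    try:
        popt, _ = curve_fit(
            lambda xx, a, b: a * xx / (b + xx),
            x, y, p0=(a0, b0),
            bounds=((1e-12, 1e-12), (np.inf, np.inf)),
            xtol=xtol, ftol=xtol, maxfev=max_iter,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    return MMFit(a=float(popt[0]), b=float(popt[1]))


def predict_population_area(fit: MMFit, population_n: int = 10_000) -> float:
    """Range area predicted for a population of ``population_n`` birds."""
    return fit.a * population_n / (fit.b + population_n)


def proportion_sampled(sample_area_km2: float, predicted_population_area_km2: float) -> float:
    """Share of the predicted population-level range covered by the sample."""
    if sample_area_km2 <= 0 or predicted_population_area_km2 <= 0:
        raise ValueError("areas must be positive")
    return sample_area_km2 / predicted_population_area_km2


def n_for_fraction(fit: MMFit, f: float = 0.95) -> int:
    """Sample size needed to represent a fraction ``f`` of the asymptotic
    area: x = f*b/(1-f) (e.g. 19*b for 95%), rounded to nearest integer."""
    if not (0.0 < f < 1.0):
        raise ValueError("f must be in (0, 1)")
    return int(round(f * fit.b / (1.0 - f)))


def representativeness_summary(
    maps: list[TimeInAreaMap],
    level: float,
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
    population_n: int = 10_000,
) -> RepresentativenessSummary:
    """Accumulation curve + MM fit + population extrapolation in one call."""
    from .spaceuse import extract_range, pool_maps

    curve = accumulation_curve(maps, level=level, n_boot=n_boot, rng=rng)
    fit = fit_mm(curve)
    sample_area = extract_range(pool_maps(maps), level).area_km2
    predicted = predict_population_area(fit, population_n)
    return RepresentativenessSummary(
        level=level,
        n_birds=len(maps),
        fit=fit,
        sample_area_km2=sample_area,
        population_n=population_n,
        predicted_population_area_km2=predicted,
        prop_sampled=proportion_sampled(sample_area, predicted),
        n_for_95pct=n_for_fraction(fit, 0.95),
    )


def _trip_second_matrix(trips, grid) -> tuple[np.ndarray, float]:
    """Per-trip fix counts per cell (rows: trips). Counts are proportional to
    seconds at a regular fix interval."""
    cell_lists = []
    for t in trips:
        r, c = grid.cell_of(t.fixes["lon"].to_numpy(), t.fixes["lat"].to_numpy())
        cell_lists.append(np.stack([r, c], axis=1))
    cells = sorted({tuple(rc) for arr in cell_lists for rc in arr.tolist()})
    index = {c: j for j, c in enumerate(cells)}
    M = np.zeros((len(trips), len(cells)))
    for i, arr in enumerate(cell_lists):
        uniq, counts = np.unique(arr, axis=0, return_counts=True)
        for (rr, cc), cnt in zip(uniq.tolist(), counts):
            M[i, index[(rr, cc)]] = cnt
    return M, grid.cell_km


def individual_consistency(
    trips,
    grid,
    level: float,
    n_boot: int = 1_000,
    rng: np.random.Generator | None = None,
) -> IndividualConsistency | None:
    """Trip-based accumulation for one bird: fitted ``b`` is the number of
    trips needed to cover half the bird's own range.

    Subsets of trips are pooled by tallying time (seconds) across the chosen
    trips, i.e. the bird's own proportion map restricted to that subsample.
    Birds with fewer than 3 foraging trips are skipped (returns None).
    """
    birds = {t.bird_id for t in trips}
    if len(birds) != 1:
        raise ValueError(f"individual consistency expects one bird, got {birds}")
    bird = next(iter(birds))
    if len(trips) < 3:
        logger.info("bird %s: only %d foraging trip(s); Michaelis-Menten fit skipped",
                    bird, len(trips))
        return None
    rng = np.random.default_rng() if rng is None else rng
    M, cell_km = _trip_second_matrix(trips, grid)
    N = M.shape[0]
    means = np.empty(N)
    for n in range(1, N + 1):
        order = np.argsort(rng.random((n_boot, N)), axis=1)[:, :n]
        seconds = M[order].sum(axis=1)
        pooled = seconds / seconds.sum(axis=1, keepdims=True)
        means[n - 1] = _range_cell_counts(pooled, level).mean() * cell_km ** 2
    curve = AccumulationCurve(unit="trips", n=np.arange(1, N + 1),
                              mean_area_km2=means, n_boot=n_boot, level=level)
    return IndividualConsistency(bird_id=bird, n_trips=N, fit=fit_mm(curve), curve=curve)
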