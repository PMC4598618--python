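"""Trend statistics: OLS, Spearman, median (LAD) regression, distance decay.

The homogenization analysis rests on three fits:

* ordinary least squares for temporal trends (richness, similarity,
  temperature versus year);
* Spearman rank correlation for monotone associations where linearity is
  not assumed;
* median (tau = 0.5) quantile regression for distance-decay slopes, which
  is robust to outlying pairs.

Median regression is solved exactly: an optimal least-absolute-deviation
simple-regression line always interpolates at least two data points, so
for moderate n we enumerate all pair lines; for large n a quantile
regression fit is polished by re-enumerating pair lines among the
smallest-residual points.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .diversity import (
    PooledCommunity,
    bray_curtis_similarity,
    cell_rng,
    jaccard_similarity,
    pair_counts,
    rarefied_pooled_draw,
)
from .survey_io import BandYearCell, LatBand

logger = logging.getLogger("trawlbeta")

EARTH_RADIUS_KM = 6371.0088

Metric = Literal["jaccard", "bray_curtis"]

#: pair-line enumeration is exact and affordable up to this many points
_EXACT_LAD_MAX_N = 200


class DegenerateFitError(ValueError):
    """Predictor (or input) is constant; the fit is undefined."""


class AlignmentError(ValueError):
    """Two matrices/series do not share the labels required to combine them."""


@dataclass
class FitResult:
    """One fitted trend.

    ``slope``/``intercept`` describe a line for OLS and quantile fits; for
    Spearman fits the rank-correlation coefficient is in ``stat`` and the
    line fields are NaN.  ``objective`` is the minimised sum of
    tau = 0.5 check-loss residuals for quantile fits.
    """

    slope: float
    intercept: float
    n: int
    method: Literal["ols", "quantile_tau50", "spearman"]
    r_squared: float | None = None
    p_value: float | None = None
    stat: float | None = None
    objective: float | None = None


def ols_fit(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """Ordinary least squares y ~ x with two-sided slope t-test (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"OLS needs n >= 3, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateFitError("constant predictor")
    if np.ptp(y) == 0:
        # flat response: slope 0 exactly, no variance explained
        return FitResult(
            slope=0.0, intercept=float(y[0]), n=n, method="ols",
            r_squared=0.0, p_value=1.0,
        )
    res = stats.linregress(x, y)
    return FitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=n,
        method="ols",
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
    )


def spearman_fit(
    x: Sequence[float], y: Sequence[float], exact: bool = False
) -> FitResult:
    """Spearman rank correlation with average ranks for ties.

    The two-sided p-value uses the t approximation
    t = r_s * sqrt((n - 2) / (1 - r_s^2)); with ``exact=True`` and n <= 9
    the full permutation distribution is enumerated instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError(f"Spearman needs n >= 4, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateFitError("constant input")
    rs, p = stats.spearmanr(x, y)
    rs = float(rs)
    if exact:
        if n > 9:
            raise ValueError("exact permutation p-value limited to n <= 9")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        perms = np.array(list(itertools.permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        num = pc @ rxc
        den = np.sqrt((pc ** 2).sum(axis=1) * (rxc ** 2).sum())
        null = num / den
        p = float(np.mean(np.abs(null) >= abs(rs) - 1e-12))
    return FitResult(
        slope=math.nan, intercept=math.nan, n=n, method="spearman",
        stat=rs, p_value=float(p),
    )


def spearman_permutation_pvalue(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo label-permutation test of |r_s|; returns (r_s, p)."""
    rng = np.random.default_rng(rng)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r_obs = float(stats.spearmanr(x, y).statistic)
    hits = 1
    for _ in range(n_perm):
        r = float(stats.spearmanr(x, rng.permutation(y)).statistic)
        if abs(r) >= abs(r_obs) - 1e-12:
            hits += 1
    return r_obs, hits / (n_perm + 1)


# ---------------------------------------------------------------------------
# median (tau = 0.5) quantile regression, solved exactly
# ---------------------------------------------------------------------------

def _check_loss(x: np.ndarray, y: np.ndarray, slope: float, intercept: float) -> float:
    """Sum of rho_0.5 residuals, rho_0.5(u) = |u| / 2."""
    return 0.5 * float(np.abs(y - intercept - slope * x).sum())


def _best_pair_line(
    x: np.ndarray, y: np.ndarray, idx: np.ndarray | None = None
) -> tuple[float, float, float]:
    """Best line through two data points under the check loss.

    Ties among optimal lines are broken by smallest |slope|, then smallest
    |intercept|.  ``idx`` restricts the candidate point pairs (the full
    objective is always evaluated on all points).
    """
    if idx is None:
        idx = np.arange(len(x))
    i, j = np.triu_indices(len(idx), k=1)
    xi, xj = x[idx[i]], x[idx[j]]
    dx = xj - xi
    keep = dx != 0
    if not keep.any():
        raise DegenerateFitError("no candidate pair with distinct x")
    slopes = (y[idx[j]] - y[idx[i]])[keep] / dx[keep]
    intercepts = y[idx[i]][keep] - slopes * xi[keep]

    # objective of every candidate line over all points, chunked for memory
    obj = np.empty(len(slopes))
    step = max(1, 2_000_000 // max(1, len(x)))
    for k in range(0, len(slopes), step):
        sl = slopes[k:k + step, None]
        ic = intercepts[k:k + step, None]
        obj[k:k + step] = 0.5 * np.abs(y[None, :] - ic - sl * x[None, :]).sum(axis=1)

    best = obj.min()
    tol = 1e-12 * max(1.0, abs(best))
    ties = np.flatnonzero(obj <= best + tol)
    order = ties[np.lexsort((np.abs(intercepts[ties]), np.abs(slopes[ties])))]
    k = order[0]
    return float(slopes[k]), float(intercepts[k]), float(obj[k])


def median_slope(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """Median (tau = 0.5) quantile regression of y on x.

    Minimises sum_i rho_0.5(y_i - a - b x_i) with rho_0.5(u) = |u|/2.
    Exact for n <= 200 via pair-line enumeration; for larger n a quantile
    regression fit seeds a pair-line refinement among the lowest-residual
    points, and the two routes agree on overlapping sizes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"median regression needs n >= 3, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateFitError("constant predictor")

    if n <= _EXACT_LAD_MAX_N:
        slope, intercept, obj = _best_pair_line(x, y)
    else:
        import statsmodels.api as sm

        qr = sm.QuantReg(y, sm.add_constant(x)).fit(q=0.5)
        resid = np.abs(y - qr.params[0] - qr.params[1] * x)
        idx = np.argsort(resid)[:40]
        slope, intercept, obj = _best_pair_line(x, y, idx=idx)
    return FitResult(
        slope=slope, intercept=intercept, n=n, method="quantile_tau50",
        objective=obj,
    )


# ---------------------------------------------------------------------------
# distance and similarity matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric great-circle distances (km) between band centroids."""

    labels: list[int]
    km: np.ndarray


@dataclass
class SimilarityMatrix:
    """Pairwise between-band similarity for one year; diagonal is NaN."""

    year: int
    labels: list[int]
    values: np.ndarray

    def pairs(self):
        """Yield (label_i, label_j, similarity) over unordered pairs."""
        for i in range(len(self.labels)):
            for j in range(i + 1, len(self.labels)):
                yield self.labels[i], self.labels[j], float(self.values[i, j])


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance on a sphere of radius 6371.0088 km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))


def band_distance_matrix(bands: Sequence[LatBand]) -> DistanceMatrix:
    """Great-circle distances between band centroids."""
    if len(bands) < 2:
        raise ValueError("need >= 2 bands")
    bands = sorted(bands, key=lambda b: b.index)
    k = len(bands)
    km = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = haversine_km(
                bands[i].centroid_lat, bands[i].centroid_lon,
                bands[j].centroid_lat, bands[j].centroid_lon,
            )
            if d == 0.0:
                logger.warning(
                    "bands %d and %d have coincident centroids",
                    bands[i].index, bands[j].index,
                )
            km[i, j] = km[j, i] = d
    return DistanceMatrix(labels=[b.index for b in bands], km=km)


def _similarity(metric: Metric, x: PooledCommunity, y: PooledCommunity) -> float:
    if metric == "jaccard":
        return jaccard_similarity(pair_counts(x, y))
    if metric == "bray_curtis":
        return bray_curtis_similarity(x, y)
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# temporal-baseline and spatial similarity series
# ---------------------------------------------------------------------------

@dataclass
class BaselineSeries:
    """Similarity of each year to the first usable year of one band.

    ``within_baseline`` is the mean similarity between two independent
    rarefied draws of the first year itself — the no-change reference level
    set by sampling noise alone.
    """

    band_index: int
    year0: int
    similarity: dict[int, float]
    within_baseline: float


def baseline_beta_series(
    cells: Sequence[BandYearCell],
    effort: int,
    metric: Metric = "jaccard",
    replicates: int = 100,
    seed: int = 0,
) -> BaselineSeries:
    """Temporal beta diversity of one band relative to its first year.

    For each later year t, the mean over replicates of the similarity
    between equal-effort rarefied draws of year0 and year t.
    """
    cells = sorted(cells, key=lambda c: c.year)
    if len(cells) < 2:
        raise ValueError("baseline series needs >= 2 years")
    band = cells[0].band.index
    if any(c.band.index != band for c in cells):
        raise ValueError("cells must all belong to one band")
    cell0 = cells[0]

    # dedicated stream for each role, keyed on cell identity
    gen0 = cell_rng(seed, band, cell0.year)
    gen0b = np.random.default_rng(
        np.random.SeedSequence(entropy=[int(seed), int(band), int(cell0.year), 1])
    )
    draws0 = [rarefied_pooled_draw(cell0, effort, gen0) for _ in range(replicates)]
    draws0b = [rarefied_pooled_draw(cell0, effort, gen0b) for _ in range(replicates)]
    within = float(np.mean([
        _similarity(metric, a, b) for a, b in zip(draws0, draws0b)
    ]))

    series: dict[int, float] = {}
    for cell in cells[1:]:
        gen_t = cell_rng(seed, band, cell.year)
        vals = []
        for r in range(replicates):
            vals.append(_similarity(
                metric, draws0[r], rarefied_pooled_draw(cell, effort, gen_t)
            ))
        series[cell.year] = float(np.mean(vals))
    return BaselineSeries(
        band_index=band, year0=cell0.year, similarity=series,
        within_baseline=within,
    )


def annual_pairwise_similarity(
    cells: Sequence[BandYearCell],
    effort: int,
    metric: Metric = "jaccard",
    replicates: int = 100,
    seed: int = 0,
) -> list[SimilarityMatrix]:
    """One symmetric between-band similarity matrix per year.

    Metrics are computed on equal-effort rarefied draws, per replicate,
    then averaged.  Years with fewer than two bands are skipped with a
    warning; a band absent in a year is simply missing from that year's
    matrix.
    """
    by_year: dict[int, list[BandYearCell]] = {}
    for c in cells:
        by_year.setdefault(c.year, []).append(c)

    matrices = []
    for year in sorted(by_year):
        ycells = sorted(by_year[year], key=lambda c: c.band.index)
        if len(ycells) < 2:
            logger.warning("year %d has < 2 bands; skipped", year)
            continue
        labels = [c.band.index for c in ycells]
        gens = {c.band.index: cell_rng(seed, c.band.index, year) for c in ycells}
        k = len(ycells)
        acc = np.zeros((k, k))
        for _ in range(replicates):
            draws = [
                rarefied_pooled_draw(c, min(effort, c.n_hauls), gens[c.band.index])
                for c in ycells
            ]
            for i in range(k):
                for j in range(i + 1, k):
                    s = _similarity(metric, draws[i], draws[j])
                    acc[i, j] += s
                    acc[j, i] += s
        values = acc / replicates
        np.fill_diagonal(values, np.nan)
        matrices.append(SimilarityMatrix(year=year, labels=labels, values=values))
    return matrices


@dataclass
class HomogenizationTrend:
    """Trend of between-band similarity through time.

    ``fit_pairs`` regresses every pair-year similarity on year (each
    unordered band pair in each year is one observation; this mirrors a
    box-plot-per-year display with one fitted line).  Pairs within a year
    share sampling conditions and are not independent, so the pair-level
    p-value is descriptive; ``fit_annual``, the OLS on the per-year mean
    similarities, is the inferential test of the trend.
    """

    fit_pairs: FitResult
    fit_annual: FitResult
    annual_mean: dict[int, float]


def homogenization_trend(
    sim_matrices: Sequence[SimilarityMatrix],
) -> HomogenizationTrend:
    """OLS trend of pairwise between-band similarity against year."""
    if len(sim_matrices) < 3:
        raise ValueError("need >= 3 years of similarity matrices")
    xs, ys = [], []
    annual: dict[int, float] = {}
    for m in sorted(sim_matrices, key=lambda m: m.year):
        vals = [s for _, _, s in m.pairs()]
        for s in vals:
            xs.append(m.year)
            ys.append(s)
        annual[m.year] = float(np.mean(vals))
    fit_pairs = ols_fit(xs, ys)
    fit_annual = ols_fit(list(annual.keys()), list(annual.values()))
    return HomogenizationTrend(
        fit_pairs=fit_pairs, fit_annual=fit_annual, annual_mean=annual
    )


def distance_decay(
    sim_matrix: SimilarityMatrix, dist_matrix: DistanceMatrix
) -> FitResult:
    """Median-regression slope of similarity against between-band distance.

    One fit per year; the year-by-year series of these slopes is the
    flattening diagnostic (slopes moving toward 0 signal homogenization).
    """
    missing = set(sim_matrix.labels) - set(dist_matrix.labels)
    if missing:
        raise AlignmentError(f"bands {sorted(missing)} missing from distance matrix")
    pos = {lab: i for i, lab in enumerate(dist_matrix.labels)}
    km, sim = [], []
    for li, lj, s in sim_matrix.pairs():
        km.append(dist_matrix.km[pos[li], pos[lj]])
        sim.append(s)
    if len(km) < 3:
        raise ValueError("distance decay needs >= 3 band pairs")
    return median_slope(km, sim)


# ---------------------------------------------------------------------------
# temperature: warming, gradient flattening, and the community link
# ---------------------------------------------------------------------------

@dataclass
class TemperatureTable:
    """Mean Q1 near-surface temperature per (band index, year)."""

    mean: dict[tuple[int, int], float]
    counts: dict[tuple[int, int], int] = field(default_factory=dict)

    @property
    def years(self) -> list[int]:
        return sorted({y for _, y in self.mean})

    @property
    def bands(self) -> list[int]:
        return sorted({b for b, _ in self.mean})


def temperature_table(cells: Sequence[BandYearCell]) -> TemperatureTable:
    """Average haul temperatures within each band-year cell.

    Cells whose hauls carry no temperature record are simply absent from
    the table (missing temperature cells are tolerated throughout).
    """
    mean: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    for c in cells:
        temps = [h.surface_temp for h in c.hauls if h.surface_temp is not None]
        if temps:
            key = (c.band.index, c.year)
            mean[key] = float(np.mean(temps))
            counts[key] = len(temps)
    return TemperatureTable(mean=mean, counts=counts)


@dataclass
class TemperatureReport:
    """Temperature structure and its covariation with community similarity.

    warming_fit
        OLS of band-year mean temperature on year (every cell one point).
    gradient_slopes / gradient_trend
        Per-year median slope of temperature on centroid latitude, and the
        Spearman trend of those slopes against year: a slope series rising
        toward 0 means the south-north gradient is flattening.
    annual_mean_diff
        Per-year mean absolute pairwise temperature difference between bands.
    temp_dissim_fit / temp_sim_fit
        Spearman association between the annual mean temperature difference
        and annual mean community dissimilarity (1 - similarity), and,
        equivalently with opposite sign, with similarity itself.  Both sign
        conventions are reported.
    """

    warming_fit: FitResult
    gradient_slopes: dict[int, float]
    gradient_trend: FitResult | None
    annual_mean_diff: dict[int, float]
    temp_dissim_fit: FitResult | None
    temp_sim_fit: FitResult | None


def temperature_analyses(
    temps: TemperatureTable,
    sim_matrices: Sequence[SimilarityMatrix],
    bands: Sequence[LatBand],
) -> TemperatureReport:
    """Link the converging temperature gradient to community homogenization."""
    sim_years = {m.year for m in sim_matrices}
    overlap = sorted(set(temps.years) & sim_years)
    if len(overlap) < 3:
        raise AlignmentError(
            "need >= 3 years with both temperature and community data"
        )
    centroid = {b.index: b.centroid_lat for b in bands}

    # (i) warming: every band-year mean temperature against year
    ys = [y for (_, y) in temps.mean]
    ts = [t for t in temps.mean.values()]
    warming_fit = ols_fit(ys, ts)

    # (ii) per-year latitude gradient of temperature, and its trend
    gradient_slopes: dict[int, float] = {}
    for year in temps.years:
        pts = [(centroid[b], temps.mean[(b, y)]) for (b, y) in temps.mean if y == year]
        if len(pts) >= 3:
            lats, tvals = zip(*pts)
            gradient_slopes[year] = median_slope(lats, tvals).slope
    gradient_trend = None
    if len(gradient_slopes) >= 4:
        yrs = sorted(gradient_slopes)
        try:
            gradient_trend = spearman_fit(yrs, [gradient_slopes[y] for y in yrs])
        except DegenerateFitError:
            logger.warning("gradient slopes constant; no trend fit")

    # (iii) mean absolute pairwise temperature difference per year
    annual_mean_diff: dict[int, float] = {}
    for year in temps.years:
        vals = [temps.mean[(b, y)] for (b, y) in temps.mean if y == year]
        if len(vals) >= 2:
            diffs = [
                abs(a - b) for a, b in itertools.combinations(vals, 2)
            ]
            annual_mean_diff[year] = float(np.mean(diffs))

    # (iv) temperature convergence vs community homogenization
    annual_sim = {
        m.year: float(np.mean([s for _, _, s in m.pairs()])) for m in sim_matrices
    }
    common = sorted(set(annual_mean_diff) & set(annual_sim))
    temp_dissim_fit = temp_sim_fit = None
    if len(common) >= 4:
        d = [annual_mean_diff[y] for y in common]
        dis = [1.0 - annual_sim[y] for y in common]
        sim = [annual_sim[y] for y in common]
        try:
            temp_dissim_fit = spearman_fit(d, dis)
            temp_sim_fit = spearman_fit(d, sim)
        except DegenerateFitError:
            logger.warning("degenerate temperature/similarity series")
    return TemperatureReport(
        warming_fit=warming_fit,
        gradient_slopes=gradient_slopes,
        gradient_trend=gradient_trend,
        annual_mean_diff=annual_mean_diff,
        temp_dissim_fit=temp_dissim_fit,
        temp_sim_fit=temp_sim_fit,
    )
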