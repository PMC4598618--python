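"""Fits (OLS, Spearman, median regression), matrices and series builders."""

import math

import numpy as np
import pytest
from scipy import optimize, stats

from trawlbeta import (
    AlignmentError,
    DegenerateFitError,
    DistanceMatrix,
    PooledCommunity,
    SimilarityMatrix,
    TemperatureTable,
    TrawlSample,
    BandYearCell,
    annual_pairwise_similarity,
    band_distance_matrix,
    baseline_beta_series,
    distance_decay,
    haversine_km,
    homogenization_trend,
    make_bands,
    median_slope,
    ols_fit,
    spearman_fit,
    temperature_analyses,
)
from trawlbeta.trends import _check_loss


class TestOlsFit:
    def test_perfect_line(self):
        x = np.arange(5.0)
        fit = ols_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_response(self):
        fit = ols_fit([1, 2, 3, 4], [5, 5, 5, 5])
        assert fit.slope == 0.0 and fit.r_squared == 0.0 and fit.p_value == 1.0

    def test_hand_normal_equations(self):
        # x=(1,2,3), y=(1,3,2): slope = 0.5, r^2 = 0.25
        fit = ols_fit([1, 2, 3], [1, 3, 2])
        assert fit.slope == pytest.approx(0.5)
        assert fit.r_squared == pytest.approx(0.25)

    def test_degenerate_and_small_inputs(self):
        with pytest.raises(DegenerateFitError):
            ols_fit([2, 2, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            ols_fit([1, 2], [1, 2])

    def test_matches_closed_form_on_random_data(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = 1.3 * x + rng.normal(size=30)
        fit = ols_fit(x, y)
        xc = x - x.mean()
        slope = float(xc @ (y - y.mean()) / (xc @ xc))
        assert fit.slope == pytest.approx(slope, rel=1e-12)


class TestSpearmanFit:
    def test_perfect_concordance_and_discordance(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman_fit(x, [2, 4, 6, 8, 10]).stat == pytest.approx(1.0)
        assert spearman_fit(x, x[::-1]).stat == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        # sum d^2 = 2 -> r_s = 1 - 6*2/(5*24) = 0.9; classic variant with
        # y=(1,3,2,5,4): d = (0,1,-1,0,... ) gives r_s = 0.8
        fit = spearman_fit([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert fit.stat == pytest.approx(0.8)

    def test_exact_permutation_pvalue_matches_enumeration(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        fit = spearman_fit(x, y, exact=True)
        # under the null all 120 rank orderings are equally likely
        import itertools

        r_obs = stats.spearmanr(x, y).statistic
        hits = sum(
            abs(stats.spearmanr(x, p).statistic) >= abs(r_obs) - 1e-12
            for p in itertools.permutations(y)
        )
        assert fit.p_value == pytest.approx(hits / math.factorial(5))

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateFitError):
            spearman_fit([1, 1, 1, 1], [1, 2, 3, 4])


def _lad_linprog(x, y):
    """Independent LAD oracle: linear program over residual splits."""
    n = len(x)
    # variables: a, b (free, split), u+, u- >= 0 with u+ - u- = y - a - b x
    c = np.concatenate([[0, 0, 0, 0], 0.5 * np.ones(2 * n)])
    A_eq = np.zeros((n, 4 + 2 * n))
    A_eq[:, 0] = 1.0
    A_eq[:, 1] = -1.0
    A_eq[:, 2] = x
    A_eq[:, 3] = -x
    A_eq[:, 4:4 + n] = np.eye(n)
    A_eq[:, 4 + n:] = -np.eye(n)
    res = optimize.linprog(c, A_eq=A_eq, b_eq=y, method="highs")
    assert res.success
    return res.fun


class TestMedianSlope:
    def test_collinear_recovery(self):
        x = np.linspace(0, 10, 9)
        fit = median_slope(x, -0.3 * x + 4)
        assert fit.slope == pytest.approx(-0.3)
        assert fit.intercept == pytest.approx(4.0)
        assert fit.objective == pytest.approx(0.0, abs=1e-12)

    def test_outlier_ignored(self):
        x = np.arange(10.0)
        y = x.copy()
        y[7] = 500.0
        fit = median_slope(x, y)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_objective_never_above_ols_line(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(3, 20))
            x = rng.normal(size=n)
            x[0] += 1.0  # ensure non-constant
            y = rng.normal(size=n)
            lad = median_slope(x, y)
            ols = ols_fit(x, y) if n >= 3 else None
            assert lad.objective <= _check_loss(x, y, ols.slope, ols.intercept) + 1e-12

    def test_matches_linear_program_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            n = int(rng.integers(3, 15))
            x = np.round(rng.uniform(0, 10, n), 3)
            if np.ptp(x) == 0:
                x[0] += 1.0
            y = np.round(rng.uniform(0, 10, n), 3)
            fit = median_slope(x, y)
            assert fit.objective == pytest.approx(_lad_linprog(x, y), abs=1e-9)

    def test_large_n_path_agrees_with_exact_path(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 250)
        y = 0.7 * x + rng.standard_cauchy(250)
        fit_big = median_slope(x, y)  # quantile-regression-seeded path
        from trawlbeta.trends import _best_pair_line

        slope, intercept, obj = _best_pair_line(x, y)  # exact enumeration
        assert fit_big.objective == pytest.approx(obj, rel=1e-9)

    def test_constant_predictor_raises(self):
        with pytest.raises(DegenerateFitError):
            median_slope([1, 1, 1], [1, 2, 3])


class TestDistances:
    def test_half_degree_latitude_separation(self):
        # 0.5 deg of latitude at constant longitude ~ 55.6 km
        assert haversine_km(55.25, -7, 55.75, -7) == pytest.approx(
            6371.0088 * math.radians(0.5), rel=1e-6
        )

    def test_matrix_symmetric_zero_diagonal(self):
        bands = make_bands(55.0, 5)
        dm = band_distance_matrix(bands)
        assert np.allclose(dm.km, dm.km.T)
        assert np.all(np.diag(dm.km) == 0)
        # triangle inequality on a meridian (equality up to rounding)
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    assert dm.km[i, j] <= dm.km[i, k] + dm.km[k, j] + 1e-9

    def test_identical_centroids_zero(self):
        assert haversine_km(55.0, -7.0, 55.0, -7.0) == 0.0


def _cells_from_sets(band, sets_by_year, lat=55.1):
    cells = []
    for year, specs in sets_by_year.items():
        hauls = [TrawlSample(
            haul_id=f"{band.index}-{year}", year=year, quarter=1,
            latitude=lat, longitude=-7.0, cpue={s: 1.0 for s in specs},
        )]
        cells.append(BandYearCell(band=band, year=year, hauls=hauls))
    return cells


class TestBaselineSeries:
    def test_identical_communities_all_one(self):
        band = make_bands(55.0, 2)[0]
        cells = _cells_from_sets(band, {y: {"a", "b"} for y in (2000, 2001, 2002)})
        bs = baseline_beta_series(cells, effort=1, replicates=5, seed=0)
        assert bs.similarity == {2001: 1.0, 2002: 1.0}
        assert bs.within_baseline == 1.0

    def test_complete_replacement_gives_zero(self):
        band = make_bands(55.0, 2)[0]
        cells = _cells_from_sets(band, {2000: {"a", "b"}, 2001: {"c", "d"}})
        bs = baseline_beta_series(cells, effort=1, replicates=3, seed=0)
        assert bs.similarity[2001] == 0.0

    def test_one_species_difference(self):
        band = make_bands(55.0, 2)[0]
        cells = _cells_from_sets(
            band, {2000: {"a", "b", "c", "d"}, 2001: {"a", "b", "c", "e"}}
        )
        bs = baseline_beta_series(cells, effort=1, replicates=3, seed=0)
        assert bs.similarity[2001] == pytest.approx(3 / 5)

    def test_single_year_raises(self):
        band = make_bands(55.0, 2)[0]
        cells = _cells_from_sets(band, {2000: {"a"}})
        with pytest.raises(ValueError):
            baseline_beta_series(cells, effort=1, replicates=3, seed=0)


class TestAnnualSimilarityAndTrend:
    def _matrices(self, values_by_year):
        mats = []
        for year, v in values_by_year.items():
            m = np.array([[np.nan, v], [v, np.nan]])
            mats.append(SimilarityMatrix(year=year, labels=[0, 1], values=m))
        return mats

    def test_identical_and_disjoint_bands(self):
        bands = make_bands(55.0, 3)
        cells = []
        cells += _cells_from_sets(bands[0], {2000: {"a", "b"}}, lat=55.1)
        cells += _cells_from_sets(bands[1], {2000: {"a", "b"}}, lat=55.6)
        cells += _cells_from_sets(bands[2], {2000: {"c"}}, lat=56.2)
        mats = annual_pairwise_similarity(cells, effort=1, replicates=2, seed=0)
        m = mats[0]
        assert m.values[0, 1] == 1.0          # identical communities
        assert m.values[0, 2] == 0.0          # disjoint
        assert np.allclose(m.values, m.values.T, equal_nan=True)

    def test_constant_similarity_flat_trend(self):
        trend = homogenization_trend(self._matrices({y: 0.4 for y in range(2000, 2005)}))
        assert trend.fit_pairs.slope == pytest.approx(0.0, abs=1e-12)

    def test_perfect_rise(self):
        years = list(range(2000, 2004))
        vals = dict(zip(years, np.linspace(0.2, 0.8, 4)))
        trend = homogenization_trend(self._matrices(vals))
        assert trend.fit_pairs.slope > 0
        assert trend.fit_pairs.r_squared == pytest.approx(1.0)
        assert trend.annual_mean == pytest.approx(vals)

    def test_trend_invariant_under_band_relabeling(self):
        rng = np.random.default_rng(0)
        mats, mats_perm = [], []
        for year in range(2000, 2006):
            k = 4
            v = rng.uniform(0, 1, size=(k, k))
            v = (v + v.T) / 2
            np.fill_diagonal(v, np.nan)
            perm = rng.permutation(k)
            mats.append(SimilarityMatrix(year=year, labels=list(range(k)), values=v))
            mats_perm.append(SimilarityMatrix(
                year=year, labels=[int(p) for p in perm],
                values=v[np.ix_(perm, perm)],
            ))
        a = homogenization_trend(mats)
        b = homogenization_trend(mats_perm)
        assert a.fit_pairs.slope == pytest.approx(b.fit_pairs.slope, rel=1e-12)


class TestDistanceDecay:
    def _sim(self, vals, labels=(0, 1, 2)):
        k = len(labels)
        m = np.full((k, k), np.nan)
        idx = 0
        for i in range(k):
            for j in range(i + 1, k):
                m[i, j] = m[j, i] = vals[idx]
                idx += 1
        return SimilarityMatrix(year=2000, labels=list(labels), values=m)

    def _dist(self, labels=(0, 1, 2)):
        return band_distance_matrix(make_bands(55.0, len(labels)))

    def test_flat_similarity_zero_slope(self):
        fit = distance_decay(self._sim([0.4, 0.4, 0.4]), self._dist())
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_linear_decay_recovered_exactly(self):
        dm = self._dist()
        km = [dm.km[0, 1], dm.km[0, 2], dm.km[1, 2]]
        sims = [0.9 - 0.002 * d for d in km]
        fit = distance_decay(self._sim([sims[0], sims[1], sims[2]]), dm)
        assert fit.slope == pytest.approx(-0.002)
        assert fit.objective == pytest.approx(0.0, abs=1e-12)

    def test_distance_offset_changes_intercept_not_slope(self):
        rng = np.random.default_rng(4)
        dm = self._dist((0, 1, 2, 3))
        k = 4
        vals = rng.uniform(0.2, 0.8, size=6)
        sm = SimilarityMatrix(year=2000, labels=list(range(k)),
                              values=np.full((k, k), np.nan))
        idx = 0
        for i in range(k):
            for j in range(i + 1, k):
                sm.values[i, j] = sm.values[j, i] = vals[idx]
                idx += 1
        fit = distance_decay(sm, dm)
        shifted = DistanceMatrix(labels=dm.labels, km=dm.km + 100.0)
        np.fill_diagonal(shifted.km, 0.0)
        fit2 = distance_decay(sm, shifted)
        assert fit2.slope == pytest.approx(fit.slope, rel=1e-9)

    def test_label_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            distance_decay(self._sim([0.4, 0.4, 0.4], labels=(0, 1, 7)), self._dist())


class TestTemperatureAnalyses:
    def _mats(self, sims_by_year, k=4):
        mats = []
        for year, v in sims_by_year.items():
            m = np.full((k, k), np.nan)
            m[np.triu_indices(k, 1)] = v
            m.T[np.triu_indices(k, 1)] = v
            mats.append(SimilarityMatrix(year=year, labels=list(range(k)), values=m))
        return mats

    def test_constant_field_all_zero(self):
        bands = make_bands(55.0, 4)
        years = range(2000, 2006)
        temps = TemperatureTable(
            mean={(b, y): 9.0 for b in range(4) for y in years}
        )
        report = temperature_analyses(
            temps, self._mats({y: 0.5 for y in years}), bands
        )
        assert report.warming_fit.slope == pytest.approx(0.0, abs=1e-12)
        assert all(v == pytest.approx(0.0, abs=1e-12)
                   for v in report.gradient_slopes.values())
        assert all(v == 0.0 for v in report.annual_mean_diff.values())

    def test_noiseless_flattening_gradient(self):
        bands = make_bands(55.0, 4)
        years = list(range(2000, 2010))
        grads = np.linspace(-0.2, 0.0, len(years))  # degC per deg latitude
        temps = {}
        for g, y in zip(grads, years):
            for b, band in enumerate(bands):
                temps[(b, y)] = 9.0 + g * (band.centroid_lat - bands[0].centroid_lat)
        report = temperature_analyses(
            TemperatureTable(mean=temps), self._mats({y: 0.5 for y in years}), bands
        )
        slopes = [report.gradient_slopes[y] for y in years]
        assert all(b > a for a, b in zip(slopes, slopes[1:]))
        assert report.gradient_trend.stat == pytest.approx(1.0)

    def test_no_overlapping_years_raises(self):
        bands = make_bands(55.0, 4)
        temps = TemperatureTable(mean={(0, 1990): 9.0, (1, 1990): 8.0})
        with pytest.raises(AlignmentError):
            temperature_analyses(temps, self._mats({2000: 0.5, 2001: 0.5, 2002: 0.5}), bands)
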