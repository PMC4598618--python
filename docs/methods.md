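# Methods

## The analysis

The pipeline treats a trawl survey as a grid of *band-year cells*: all
hauls taken in one 30′ latitudinal band in one year.  Bands are
half-open intervals `[lat_lo, lat_hi)` — lower edge inclusive — so a
haul on a boundary belongs to exactly one band.  Every input haul is
either assigned to one cell or counted in exactly one drop category
(outside all bands, wrong quarter, excluded year, or in a cell thinner
than `min_hauls_per_year`); the reconciliation totals are logged and the
filter is configuration-driven rather than hard-coding any particular
survey's bad years.

Sampling effort differs between cells, and incidence-based indices are
effort-sensitive, so all diversity quantities are computed at a common
effort: by default the smallest post-filter cell size (`effort_policy:
"min"`), or a fixed integer for cross-dataset comparability.  The haul
is the sampling unit.  Rarefaction draws hauls uniformly without
replacement; richness is reported as the Monte-Carlo mean together with
the analytic hypergeometric expectation

    E[S] = sum_i [ 1 - C(m - m_i, n) / C(m, n) ]

(`m` hauls available, `n` drawn, species *i* present in `m_i` hauls),
which the Monte-Carlo estimate is tested against.  Similarities are
computed *per rarefied draw and then averaged* — averaging pooled
communities first would inflate incidence-based similarity, because a
species seen in any draw would count as present in all of them.  No
extrapolation beyond observed effort is offered.

Incidence is "summed CPUE > 0" with no minimum-abundance threshold.
Comparing two empty assemblages raises an error instead of returning a
placeholder 0 or 1; a silent value would leak into trend fits.

### Similarity, partition, turnover share

For incidence counts `a` (shared), `b`, `c` (unique to either side):
Jaccard similarity `a/(a+b+c)`; Jaccard dissimilarity splits as

    beta_jac = (b+c)/(a+b+c)
    beta_jtu = 2 min(b,c) / (a + 2 min(b,c))      (turnover)
    beta_jne = beta_jac - beta_jtu                 (nestedness)

with `beta_jtu = 0` when `a + 2 min(b,c) = 0`.  Additivity holds to
1e-12 and is property-tested.  Bray–Curtis similarity is
`1 - Σ|x_s - y_s| / Σ(x_s + y_s)` over the species union.  The
*turnover share* of a set of pairwise comparisons is the mean of
`beta_jtu / beta_jac` over comparisons with `beta_jac > 0` (identical
pairs carry no dissimilarity to attribute and are excluded, counted in
the log).  With rarefaction replicates, the partition components are
replicate-averaged per pair before the share is formed.

### Trend fits

* **OLS** (`ols_fit`): slope, intercept, `r² = 1 − SS_res/SS_tot`,
  two-sided *t*-test on the slope with `n−2` df.  A constant response
  returns slope 0, r² 0, p 1; a constant predictor raises.
* **Spearman** (`spearman_fit`): average ranks for ties; two-sided p via
  `t = r_s sqrt((n−2)/(1−r_s²))`, with an exact permutation option for
  n ≤ 9.  A Monte-Carlo label-permutation test is available separately.
* **Median regression** (`median_slope`, τ = 0.5): minimizes
  `Σ ρ_0.5(y_i − a − b x_i)` with `ρ_0.5(u) = |u|/2`.  An optimal
  least-absolute-deviation simple-regression line interpolates at least
  two data points, so for n ≤ 200 the solver enumerates all pair lines
  and is exact; ties among optima are broken by smallest |slope|, then
  smallest |intercept|.  For larger n a quantile-regression fit
  (statsmodels) seeds a pair-line refinement among the 40
  smallest-residual points; the two routes agree on overlapping sizes
  (tested), and the solution is verified against an independent
  linear-programming oracle in the test suite.

### Homogenization trend: which p-value is inferential

`homogenization_trend` reports two fits of between-band similarity
against year.  The *pair-level* fit treats every unordered band pair in
every year as one observation, matching the conventional
box-plot-per-year display with a single fitted line; its slope and r²
are the headline descriptive numbers.  But pairs within a year share
the year's sampling conditions and are not independent — measured on the
stationary generator, the pair-level p-value rejects a true null ~33% of
the time at α = 0.05.  The *annual* fit — OLS of the per-year mean
similarity on year, n = number of years — uses independent observations
and shows a ~3–6% empirical type-I rate.  The annual fit is therefore
the pipeline's significance test for homogenization; the pair-level
p-value is reported but descriptive.

### Distance decay and flattening

Between-band distances are great-circle (haversine, Earth radius
6371.0088 km) between band centroids.  All bands share one configured
centroid longitude (default: the mean haul longitude of the dataset), so
distance expresses latitudinal separation; the decay slope is invariant
to adding a constant to all distances (tested).  Per year, the decay fit
is the median-regression slope of similarity on km over all band pairs
(≥ 3 pairs required).  The flattening diagnostic is the OLS trend of
these slopes against year: decay slopes are negative, so a significant
*positive* trend (slopes rising toward zero) is the per-run flattening
trigger.

### Temperature link

Per band-year, haul temperatures are averaged; cells without temperature
records are simply absent (the analyses tolerate missing cells).  The
report contains (i) OLS of band-year mean temperature on year; (ii) the
per-year median-regression slope of temperature on centroid latitude and
the Spearman trend of those slopes against year (gradient flattening);
(iii) the per-year mean absolute pairwise temperature difference between
bands; (iv) the Spearman association between annual mean temperature
difference and annual mean Jaccard dissimilarity (1 − similarity),
restricted to overlapping years.  Because a *decline* in temperature
differences accompanying a *decline* in dissimilarity is a positive
association on the dissimilarity scale but the mirror image on the
similarity scale, both sign conventions are reported
(`temp_dissim_fit`, `temp_sim_fit`) rather than privileging one.

p-values throughout are descriptive outputs; no multiple-testing
correction is applied.  Per-band α-trend displays flag slopes at
two-sided α = 0.05.

### Determinism

One pipeline seed drives everything.  Random draws use per-cell
substreams keyed by `(seed, band index, year)` (plus a role component
where two independent streams of the same cell are needed, e.g. the
within-first-year baseline), so results do not depend on the order in
which cells are processed, and reruns with the same config+seed are
byte-identical, including row order in every CSV.

## The synthetic survey generator

The generator emulates the shape of a quarter-1 groundfish survey:
9 bands × 27 years × 10 hauls per cell, a 131-species pool, CPUE
abundances, and a south–north temperature gradient that can converge.

* **Climatology** `T(b,t)`: linear interpolation between a southern and
  a northern endpoint, each warming linearly at its own rate.  Defaults:
  south 10.0 °C, north 7.6 °C initially (2.4 °C over ~5° latitude);
  warming 0.01 (south) and 0.09 (north) °C/yr, i.e. a mean rise of
  ≈ 1.3 °C over 27 years with near-complete gradient convergence.
* **Recorded temperature**: climatology plus Gaussian *measurement*
  noise (sd 0.15 °C) per band-year.  Species respond to the climatology,
  not the measured value.  This separation is deliberate: if the niche
  filter saw the measured noise, years whose band temperatures happened
  to spread further apart would also be years of higher compositional
  dissimilarity, and the temperature-difference/dissimilarity
  association would fire even in a stationary climate.  With
  measurement-only noise the stationary regime is a true independence
  null for all three detectors (measured false-trigger rates 0–5%).
* **Niche model**: species *s* has thermal optimum `opt_s` and expected
  CPUE per haul `base_s · exp(−(T − opt_s)²/(2σ²))`, σ = 0.6 °C.
* **Optima**: stratified (jittered-grid) over the whole-study
  climatological range ± 2σ — marginally uniform, but with an even
  realized density.  Spanning the *travelled* range keeps edge bands
  supplied with species to gain as water warms; the stratification, and
  a golden-ratio (low-discrepancy) assignment of abundance ranks to
  positions along the temperature axis, make expected richness flat in
  temperature.  Without these two choices the finite 131-species pool
  produces realized richness-vs-temperature profiles bumpy enough that
  warming creates spurious richness trends in a large fraction of runs,
  defeating the regime whose point is richness stationarity.  Marginal
  distributions are unchanged: optima uniform, abundances lognormal.
* **Abundances**: lognormal (μ = −3.0, σ = 1.5 on the log scale),
  giving the few-dominants/many-rares structure of trawl communities;
  calibrated once so the default survey yields a mean rarefied richness
  of ≈ 21.5 species per band-year from the 131-species pool.
* **Observation**: CPUE per haul is negative binomial with the niche
  mean and dispersion (size) 1.0 — trawl catches are overdispersed;
  large dispersion recovers the Poisson limit (tested against the niche
  expectation by a law-of-large-numbers check).
* **Regimes**: `homogenization_on` is derived as
  `warming_rate_north > warming_rate_south`.  `stationary_config()`
  zeroes both rates (exchangeable years: the null).
  `symmetric_warming_config()` (default 0.03 °C/yr both ends) drifts
  composition without trending the gradient or expected richness — the
  regime that dissociates flat α diversity from steady temporal β.

Measured on 100-seed ensembles: the converging regime triggers the
homogenization trend, the decay flattening, and the temperature
association in ≈ 100% of runs; the stationary regime in 0–5%; the
symmetric regime keeps richness trendless in ~93–95% of runs while the
baseline similarity declines in ~100%.

### What the generator does not emulate

No dispersal or colonization dynamics (presence is an independent niche
draw each year, so temporal autocorrelation beyond the climate trend is
absent); no species interactions, fishing mortality, or within-band
spatial structure; haul positions are uniform within bands.  Passing the
simulation-based tests therefore shows the *analysis* recovers signals
of this kind at realistic sizes and noise levels — not that real survey
data contain them.

## Problem sizes and numerical choices

The simulation ensembles use 100 seeds per regime with one rarefied
draw per similarity (cells are equal-sized in the default generator, so
rarefaction at minimum effort is the deterministic full pool);
rarefaction oracle checks use 1000 Monte-Carlo replicates; the
median-regression exactness check covers 500 random instances at
n ≤ 14 against a brute-force oracle plus a linear-programming
cross-check at 1e-9.  Tie-breaks, degenerate inputs (constant
predictors, empty assemblages, single-year bands, missing temperature
cells) and the undefined-index policy are each exercised in the unit
tests.

## Known limitations

* Sørensen-family partitioning, multi-site (> 2 assemblage) β formulas,
  and coverage-based rarefaction are out of scope.
* The pair-level homogenization p-value is anticonservative by
  construction (see above); downstream users should quote the annual
  fit for inference.
* Quantile-regression p-values are not produced (the exact solver
  reports slope, intercept and objective; significance of decay
  flattening is assessed on the year series of slopes instead).
* With very thin cells (one haul) the within-year baseline similarity
  is degenerate at 1; `min_hauls_per_year` exists to filter such cells
  in real data.
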