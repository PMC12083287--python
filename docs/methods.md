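# Methods

`greenmobility` implements a desk-scale, fully synthetic re-creation of a
city-level analysis linking urban green space to pandemic-era mobility: two
green-space metrics computed from gridded population and land-cover data, a
local spatial-association (hot/cold spot) analysis of mobility indices, and
Gaussian spatial mixed models with moderation terms. Every stage is exercised
on data from the package's own generator, whose ground truth is recorded, so
the statistical behaviour of each estimator can be verified rather than
assumed.

## Green-space metrics

A city is a pair of co-registered grids: population `P_i >= 0` (persons per
cell) and green fraction `g_i in [0, 1]`. The **coverage rate** of cell *i*
is the mean green fraction over all cells whose centres lie within a buffer
radius of cell *i*'s centre (cell *i* included):

    G_i = mean{ g_j : d(i, j) <= r }.

Cells outside the raster contribute nothing, so edge cells average over their
truncated neighbourhood. The default buffer is `r = 500 m`, a conventional
walking-access distance; it is exposed everywhere as a parameter. With
`r = 0` the coverage rate is the green fraction itself.

**Population-weighted exposure** is the coverage rate experienced by the
average resident,

    GE = sum_i P_i G_i / sum_i P_i in [0, 1].

Zero-population cells carry no weight but still contribute to their
neighbours' coverage rates: coverage is a landscape property, weighting a
population property.

**Green-space Gini** is the population-weighted Gini index of the coverage
rates: with `p_i = P_i / sum P` and `mu = sum_i p_i G_i`,

    Gini = sum_i sum_j p_i p_j |G_i - G_j| / (2 mu).

The implementation uses the exactly equivalent sorted Lorenz-curve form
(O(n log n)); the O(n^2) pairwise form serves as an independent oracle in the
tests (agreement to 1e-10). Conventional direction: 0 = every resident sees
identical coverage, larger = more unequal. A greenless city (`mu = 0`)
returns Gini 0 rather than NaN and is flagged, so downstream models stay
finite. Tiny negative values from floating-point summation are clipped to 0;
the convolution ratio behind `G_i` is likewise clipped into [0, 1].

## Trajectories

Raw mobility series are per-city, per-mode daily indices on an arbitrary
positive scale. `normalize_to_baseline` multiplies each series by
`100 / value(baseline date)`, so the baseline date reads exactly 100 and
values above/below 100 mean stronger/weaker use of the mode than at baseline.
`aggregate_monthly` reduces daily records to calendar-month arithmetic means
(median available as an option) over the analysis window — by default
February 2020 (month 1) through December 2021 (month 23) — dropping records
outside it. City-months with no daily records are absent, not imputed; a
count is logged. A **turning point** of a mean trajectory is a strict local
minimum: month *t* with `y(t) < y(t-1)` and `y(t) < y(t+1)`. Plateau minima
(ties) are deliberately not reported, since the definition requires a strict
change of slope on both sides.

## Hot/cold spot analysis

Spatial weights over city centroids use great-circle (haversine, R = 6371 km)
distances. Two binary schemes are provided, both with self-weight 1 (the
"star" convention): a distance band (`w_ij = 1` iff `d_ij <= band`), whose
default band is the smallest distance leaving no city neighbourless (the
maximum nearest-neighbour distance), and k-nearest-neighbours symmetrized by
union. The Getis-Ord Gi* z-score for site *i* is

    z_i = (sum_j w_ij x_j - xbar W_i) / ( S sqrt[(n S1_i - W_i^2)/(n - 1)] ),

with `W_i = sum_j w_ij`, `S1_i = sum_j w_ij^2`, `xbar` the plain mean and `S`
the population standard deviation. Constant values (S = 0) and neighbourhoods
spanning the whole sample (the 0/0 case, e.g. an all-ones weight matrix) are
rejected with explicit errors. Classification is two-sided at |z| >= 1.645 /
1.960 / 2.576 (90 / 95 / 99%, boundary inclusive), hot for positive z, cold
for negative; p-values come from the normal approximation, whose size the
acceptance suite verifies by permutation (~5% of |z| > 1.96 under exchangeable
values). No multiplicity correction is applied by default, matching the
classic Gi* workflow; the per-slice outputs make any correction easy to add.

## Gaussian spatial mixed model

For one mode, rows are city x month observations:

    y = X beta + Z b + eps,
    b ~ N(0, sigma_b^2 R(rho)),  R_cc' = exp(-d_cc' / rho),
    eps ~ N(0, sigma_e^2 I),

with `Z` the city-membership matrix and `d` great-circle distance in km.
The exponential kernel is the default geostatistical choice; Gaussian and
spherical families are available. The random structure is spatially
correlated city intercepts plus independent residuals (an alternative —
independent city intercepts with a spatially correlated error — would change
only the interpretation of rho, not the fitting machinery).

Estimation profiles beta out by generalized least squares and maximizes the
restricted likelihood (REML default; ML available) over
`(log sigma_b^2, log rho, log sigma_e^2)` with Nelder-Mead from three
moment-informed starting points (a between/within decomposition of OLS
residuals and two bracketing splits), stopping at 1e-8 on the objective. All
likelihood algebra is reduced to C x C city blocks with the Woodbury identity
and the matrix determinant lemma, so a 50-city x 23-month fit takes well
under a second. Fixed-effect covariance is `(X' V^-1 X)^-1`; inference is
Wald (normal), with stars at p < 0.10 / 0.05 / 0.01. Individual variance
components can be held fixed (`fixed=`), which is how the test suite verifies
the exact OLS limit at `sigma_b^2 = 0` (REML then reproduces the OLS residual
variance, and estimates and standard errors match OLS to numerical
precision). The (sigma_b^2, rho) profile is nearly flat when the spatial
signal is weak — a generic feature of this likelihood — so variance
components are reported with that caveat while fixed effects remain stable.

Design construction: one row per city x month with complete data (listwise
deletion, counts reported); urban-form category dummy-coded against its
alphabetically first observed level; seasonality as calendar month-of-year
dummies against the first observed month; continuous moderators mean-centred
before interaction products (main effects stay on their raw scale), which
keeps main effects interpretable at the moderator mean. The model suite runs
three base models (driving, walking, transit), the exposure x Gini
interaction (model family 4), and five moderation families — GDP, HDI,
population density, policy stringency, pandemic severity — each interacting
the moderator with both green metrics, for every mode (21 fits). The mean
variance inflation factor is reported per fit; under the generator defaults
it stays below 4.

**Identifiability.** The base model carries ~16 city-level columns
(intercept, two green metrics, seven static covariates, up to seven
urban-form dummies), so it needs comfortably more cities than that, and at
least three countries (with two, the two national-level covariates span the
same contrast and the design is collinear). The default study size of 50
cities satisfies both with margin.

## Synthetic-data generator

The generator is the package's definition of the study conditions; all draws
are recorded as ground truth.

* **Rasters.** Population is `exp(log_mean + log_sd * F)` with `F` a
  standardized Gaussian-smoothed white-noise field (default log_mean 4,
  log_sd 1, smoothing range 4 cells on a 32 x 32 grid of 100 m cells) —
  clustered, strictly positive counts. Green cover is binary: cells where a
  second smooth field (range 5 cells) exceeds its q-quantile are green;
  q defaults to 0.7 and is jittered per city by +-0.15 (clipped to
  [0.02, 0.98]) to create between-city variation in green provision. The
  saturated cases q = 0 / q = 1 are honoured exactly. This is the simplest
  reproducible random-field construction with controllable clustering; it
  makes no attempt to match real population or land-cover marginals.
* **Sites and countries.** City coordinates are uniform over longitude and
  inhabited latitudes [-60, 75]; countries are k-means clusters of
  coordinates (about one per seven cities), with singleton clusters merged
  into the nearest country because a one-city country makes its national
  covariates collinear with any city-unique dummy. GDP per capita (kUSD,
  log-normal around ~20k) and HDI (uniform 0.45-0.95) are drawn per country
  and constant within it; night-light brightness, density (10^3 persons/km^2,
  log-normal), PM2.5 (log-normal around 25 ug/m^3), median age, sex ratio
  (males per 100 females, ~N(99, 3)) and an 8-level urban-form category vary
  by city.
* **Time-varying covariates.** Policy stringency follows a global
  ramp/plateau/relaxation template scaled per city and clipped to [0, 100];
  the cumulative infection rate is a non-decreasing per-city series reaching
  2-30% of the population by the end of 2021.
* **Panel.** Monthly city means follow the index-scale mixed model
  `y = 100 + x'beta + b_c + eps` with `b` drawn from the exponential spatial
  covariance (defaults sigma_b^2 = 25, rho = 800 km, sigma_e^2 = 16 — city
  effects of ~5 index points with continental-scale correlation, monthly
  noise of ~4 points). Daily values add iid N(0, 4^2) noise around the
  monthly mean. Emitted raw values are the index times an arbitrary positive
  per-city scale (log-normal, sd 0.3 on the log scale), with the baseline
  date (2020-01-13, the month before the analysis window) noise-free at
  100 x scale, so baseline normalization inverts the scale exactly and
  recovery of the planted coefficients is not distorted. The default fixed
  effects for green exposure and green Gini are the headline base-model point
  estimates for each mode (38.52/50.48 driving, 46.82/58.88 walking,
  75.62/162.07 transit, index points per unit of the metric); the remaining
  covariates carry modest field-plausible values, and a documented default
  moderation magnitude (walking exposure x severity = 148.71) is used by the
  power study. Interaction contributions are generated with mean-centred
  components, matching the design-matrix convention, so planted interaction
  coefficients are directly comparable to fitted ones.

**What the generator does and does not emulate.** It reproduces the
*structural assumptions* of the analysis — clustered population, thresholded
green cover, baseline-100 indices, monthly linear model with spatially
correlated city effects — with known truth. It does not reproduce real
marginal distributions, real city boundaries, missing-data patterns,
reporting artefacts, or any behavioural feedback between covariates and
mobility; the synthetic index *level* is likewise not calibrated to observed
pandemic trajectories. Passing tests therefore demonstrate that the
estimators are correct and calibrated under the stated model, not that the
substantive findings would replicate on real data.

## Calibration experiments

`greenmobility.experiments` packages the replicate studies the acceptance
suite and `scripts/acceptance.py` run: `metric_extremes` (metric ranges over
a 1000-raster randomized ensemble), `recovery_study` (50 replicate 50-city x
23-month studies; bias of every planted continuous coefficient within 3
Monte-Carlo standard errors, pooled 95% Wald coverage within [0.90, 0.99]),
and `moderation_study` (size ~5% at alpha = 0.05 with zero planted
interactions; power >= 90% for the documented default moderation effect).
Replicate r uses seed `base_seed + r`. These sizes keep the full suite and
the acceptance script to a couple of minutes each on one CPU.

## Known limitations

* Variance-component inference is asymptotic; no small-sample (e.g.
  Kenward-Roger) corrections, no Bayesian estimation, no space x time
  covariance.
* Gi* significance uses the normal approximation without multiplicity
  correction by default.
* The buffer-mean coverage rate is one of several plausible exposure
  schemes (no distance decay within the buffer).
* The generator's binary green layer and uniform site placement are
  deliberate simplifications; see above for what that implies about external
  validity.
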