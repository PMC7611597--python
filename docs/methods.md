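# Methods

## Scientific setting

Early-intervention-in-psychosis (EIP) services treat people presenting
with a first episode of psychosis (FEP). Planning those services requires
forecasts of how many new cases each commissioning area will see per year,
and of the wider demand funnel: people *referred* for suspected psychosis,
the subset *assessed*, the subset who commence *treatment*, and the subset
of treated who meet operational diagnostic criteria (*probable* FEP,
taken as 86% of treated). FEP incidence varies strongly with age, gender
and ethnicity and with area-level social environment (deprivation, social
fragmentation, population density, cannabis-use prevalence), so a
stratified small-area model can turn demographic projections into local
demand forecasts.

## Incidence model

For each small-area × age-band × gender × ethnicity stratum *j*:

    y_j ~ Poisson(mu_j),   log mu_j = log PY_j + x_j' beta

* `PY_j` — person-years at risk, entered as an offset so coefficients act
  on rates; strata with `PY_j = 0` are excluded from fitting (their
  predictions are exactly zero).
* Individual-level terms (all candidate models): age band (11 bands,
  16–17 … 60–64; reference 16–17), gender (reference female), their full
  interaction, and ethnic group (9 groups; reference White British), all
  treatment-coded.
* Area-level terms (model-specific): deprivation, social fragmentation,
  regional cannabis prevalence, population density. Continuous covariates
  are z-scored using means/s.d. computed over unique areas (the sampling
  unit of an area covariate); the constants are stored on the design and
  reused verbatim at prediction time, never re-estimated on projection
  data. Deprivation may enter linearly, with an added quadratic term
  (default, capturing convexity of risk on the log scale), or as decile
  categories.

The model registry defines six candidates: model 1 individual terms only;
2 +deprivation; 3 +deprivation+cannabis; 4 +deprivation+fragmentation+
cannabis (the default forecasting model); 5 = 4+density; 6 = deprivation+
density. The registry is overridable.

### Priors

Independent Gaussians on the log-RR scale. Defaults: N(0, 1) for every
slope — weak on the RR scale (95% mass in RR 0.14–7.1) yet enough to
regularise sparse cells — and N(0, 10²) for the intercept, which is a
baseline log-rate rather than a log-RR and must not be shrunk toward zero.
The cannabis-prevalence effect carries an informative default,
N(log 1.4, 0.15²), encoding the prior epidemiological evidence on cannabis
use and psychosis risk; regional prevalence alone (tens of regions) is
weakly informative, so this prior materially drives that posterior. All
priors are configuration-driven; the shipped values are package defaults,
not estimates from any confidential source.

### Posterior approximation

The posterior is approximated by a Gaussian centred at the posterior mode
with covariance equal to the inverse negative Hessian of the log-posterior
(Laplace approximation — the same approximation family as nested-Laplace
GLM machinery). Numerical choices:

* Newton iteration with analytic gradient/Hessian, step-halving for
  monotonicity; convergence at gradient norm < 1e-8, iteration cap 100.
  Non-convergence raises an error reporting the gradient norm.
* If the curvature's smallest eigenvalue falls below 1e-12 of the largest,
  the fit first looks for a near-collinear column pair (off-diagonal
  curvature correlation > 0.999) and names it in the error; otherwise a
  ridge of 1e-8 is added and logged.
* Joint uncertainty: S = 1000 draws `beta_s = mode + L^{-T} z`,
  `z ~ N(0, I)`, with `L` the Cholesky factor of the curvature —
  reproducible under the supplied seed and preserving cross-parameter
  correlation.

The Gaussian approximation is cross-checked by an adaptive random-walk
Metropolis sampler on the identical log-posterior (proposal = Laplace
covariance scaled by 2.38²/p, global scale adapted toward 0.234 acceptance
during burn-in; 4 chains; split-chain R̂ < 1.05 required for a usable
result). On designs of ≤ 40 coefficients where every coefficient is
informed by tens of cases, posterior means agree within 0.05 on the log
scale; for coefficients informed by only a handful of cases the true
posterior is left-skewed and its mean sits below the Laplace mode by
roughly `digamma(k) − log(k)` (≈ −0.1 at k = 5 cases), which is the known
limit of the approximation.

### Model adequacy

* DIC = D̄ + pD with D(β) = −2·Poisson log-likelihood, D̄ the mean
  deviance over draws and pD = D̄ − D(β̄); at least 100 draws required.
* Pearson dispersion Σ(y−μ̂)²/μ̂ over fitted cells divided by residual
  d.f.; verdict "overdispersed" above 1.5 (configurable). A
  negative-binomial maximum-likelihood fit of the same design (via
  statsmodels) is reported for comparison. The statistic only has power
  when cell means are not tiny; at sparse stratification it concentrates
  near 1 regardless (documented in the tests by using denser cells).
* Covariate screening: a candidate area covariate added to a base model is
  dropped when its 95% credible interval on the RR scale contains 1.
  Constant covariates are rejected as non-estimable. In the default
  scenario this reproduces the intended behaviour: own-group ethnic
  density and area inequality (both generated null) are dropped, cannabis
  is kept.

## Prediction, aggregation, validation

Per draw s and projection stratum j, `lambda_js = PY_j exp(x_j' beta_s)`.
Aggregation sums within each draw first (area→CCG→national, optional
gender / broad-age 16–64, 16–35, 36–64 / ethnicity splits), then takes
means and 2.5%/97.5% quantiles across draws — intervals refer to sums,
never sums of per-stratum bounds. Where a commissioning area serves a
restricted age range, age bands outside it are dropped before summation.
Rates are count/PY × 100 000; zero-exposure groups report absent rates.
Reported intervals summarise the expected counts (parameter uncertainty
only); a posterior-predictive mode adding Poisson noise exists in the
cascade forecaster as a sensitivity option.

External validation derives probable counts from observed treated
case-loads (`probable = round(treated × 0.86)`, half-up, fraction
configurable), then computes: national predicted−observed differences
(absolute and percent, overall and by gender/broad age/ethnicity);
CCG-level Pearson r, r², RMSE on counts; a weak-calibration slope from OLS
of observed on predicted with intercept (slope 1 = perfect weak
calibration; noise in the observed response does not attenuate this
direction of regression); and cumulative banded rate differences (|d| ≤ 10
and ≤ 20 per 100 000 person-years, closed bands). RMSE is computed on
counts, flagged in the report metadata. Commissioning areas with known
data problems are removed by an exclusion list with an audit trail;
unknown ids warn rather than fail.

Missing observed ethnicity is imputed by allocating each area's
unknown-ethnicity bucket to ethnic groups in proportion to the within-area
known distribution, using largest-remainder rounding so totals are
conserved exactly (deterministic); a multinomial mode samples the
allocation for sensitivity analyses. Areas with no known-ethnicity cases
fall back to the national distribution (logged).

## Cascade forecasting

Cascade ratios divide observed referred/assessed/treated totals by the
derived probable total (nationally by default; per-CCG optionally — the
national level is the one fully determined by published service totals).
Ratios are applied per posterior draw as deterministic multipliers, so the
ordering referred ≥ assessed ≥ treated ≥ probable holds draw-wise by
construction; an optional Poisson-noise mode exists for sensitivity. With
fixed coefficients the model is log-linear in exposure, so uniform
denominator growth g per year moves every case-load by exactly g^k over k
years — a useful structural check. Per-10-treated summaries round half-up.

## Synthetic study scenarios

The generator emulates the four pipeline inputs under a configurable
`ScenarioConfig`; its defaults are the study conditions the package is
tested under:

* **Scale**: 750 small areas in 25 regions and 30 commissioning areas;
  total exposure 4 515 379 person-years; baseline rate calibrated so the
  expected total case count is 1638 (the scale of the pooled English
  catchment studies that seed the real model). Area exposure shares are
  log-normal (σ = 0.5); age structure follows an England-like 16–64
  profile; genders split evenly; per-area ethnic composition is Dirichlet
  (concentration 30) around England-like national shares, which also
  yields the own-group ethnic-density covariate.
* **Covariate marginals** (unobservable from published aggregates, chosen
  once as field-plausible): deprivation and social fragmentation standard
  normal across areas — so effects per 1 s.d. are directly interpretable;
  population density log-normal (median ≈ 3000/km², σ = 1); regional
  cannabis prevalence uniform on 6–14%; inequality standard normal.
* **True effects**: the generative linear predictor is evaluated through
  the same design-matrix code used at fit time, so generative and fitted
  coefficients share one vocabulary and standardisation by construction.
  Defaults: canonical FEP age-incidence curve (peak at 20–24) with a young
  male excess that attenuates with age; ethnic-group RRs led by Black
  Caribbean 4.80 and Black African 3.33; deprivation 0.15 + 0.05·z² per
  s.d. (convex); fragmentation RR 0.92/s.d.; cannabis RR 1.41/s.d.;
  density, ethnic density and inequality null — making the four-covariate
  model the data-generating model, consistent with the screening outcome.
* **Projections**: person-years grow deterministically as
  `baseline × g^(year − 2017)`; growth patterns can target stratum subsets
  (default 0.5%/year everywhere). Density is recomputed per year from
  projected population; other covariates stay at baseline.
* **Observed cascade**: true probable counts per commissioning area (age
  bands outside the served range excluded; 20% of areas serve 16–35 only)
  are scaled by multipliers (2.8369, 2.5494, 1.1628 per probable case —
  the ratios implied by published national service totals) with Poisson
  increments preserving the nested ordering by construction; treated cases
  are spread over strata multinomially and each loses its ethnicity label
  independently with probability 0.102. A zero-noise switch replaces all
  sampling with largest-remainder rounding for exact tests.

What the generator does **not** emulate: spatial autocorrelation of
covariates or risk, cohort-component demographic projection (growth is a
deterministic multiplier), seed data covering only a subset of areas
(the synthetic seed covers all areas), secular change in age-at-contact,
and service-side artefacts (capacity limits, waiting times, coding
drift). Passing tests therefore demonstrate the statistical machinery is
correct and well calibrated under the assumed data-generating process, not
that real service data meet those assumptions — in real extracts the
calibration slope and banded differences will be worse than
self-validation suggests.

## Problem sizes used in tests

Most tests run a structurally complete reduced scenario (60 areas,
~600 000 person-years, ~600 expected cases, < 1 s per fit). Coefficient
recovery runs at full study scale (≈148 500 strata, ~1638 expected cases)
with 5 replicate fits; the Metropolis cross-check uses a denser 5-band ×
5-group design so every coefficient is informed by tens of cases. The
acceptance script uses 5 replicates for the ethnicity and cannabis effects
and 10 for the smaller fragmentation effect.

## Known limitations

* The Laplace approximation is exact only in the Gaussian limit; its mode
  overstates the posterior mean of log-RRs informed by very few cases.
* DIC is the only information criterion provided (no WAIC/LOO), matching
  the methodology the package implements.
* Intervals condition on the denominator projections; projection
  uncertainty is not propagated.
* No spatially structured random effects; area effects are fully captured
  by the measured covariates.
* Under-16, homeless and prison populations are outside the modelled
  population.
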