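# Methods

`phenoshift` estimates long-term shifts in the timing of peak abundance of
estuarine taxa (fish, zooplankton, phytoplankton) from monthly monitoring
series, relates those shifts to local temperature and salinity trends, and
classifies each population as tracking or not tracking its climate.  This
note records the model, the conventions and numerical choices, what the
synthetic generator does and does not emulate, and the package's known
limitations.

## From monthly series to yearly phenology

The analysis atom is one taxon's monthly abundance at one station.  Series
enter only if they have at least `min_years = 10` *qualifying* years, a year
qualifying when at least `min_months_per_year = 6` months carry a
non-missing value.  Ten years is the minimum span at which a linear drift in
peak timing is separable from interannual noise in oscillating monthly
data; the six-month rule guards the peak-date estimate against sparsely
sampled years while tolerating seasonal program gaps.  Both are
configurable.

The yearly phenology statistic is the day-of-year of the 15th of the month
with the maximum abundance (ties to the earliest month; leap years
respected).  Monthly data cannot resolve timing below the month, and the
mid-month stamp is the unbiased within-month placement.  A year with fewer
observed months than the threshold, or with no positive abundance, yields
no record.

**Circular unwrapping.**  Taxa peaking near the calendar boundary would
otherwise show a spurious ±350-day jump when a December peak drifts into
January.  Peak days are therefore unwrapped per series: each value is
shifted by an integer multiple of its own year's length so it lands within
half a year of the series' circular-mean peak date, and the whole series is
then shifted by the minimal non-negative multiple of 365 days keeping every
adjusted value ≥ 1.  The second step is a pure anchoring convention — it
leaves all within-series differences (hence every correlation) unchanged —
and makes boundary-free series come back exactly unadjusted.  The raw
(no-unwrap) variant stays available behind `unwrap=False` for sensitivity
checks.  The applied offset is stored per record so the calendar date is
always recoverable.

**Climate covariates.**  Two temporal scales per station-year: the annual
mean over available months, and a seasonal mean over the window
peak-month ± 1, wrapping within the same calendar year (a January peak
averages that year's December, January, February).  The one-month
half-window is the narrowest window that is robust to single missing
months; wrapping within the calendar year keeps the covariate a function of
(station, year, month-of-peak) and avoids pulling values from years outside
the correlation's year set.

## Effect sizes and their covariance

Per stratum (taxon × station × estuary × covariate × scale) three Pearson
correlations are computed on a single common set of complete years: PT
(peak day vs. year), CT (covariate vs. year), PC (peak day vs. covariate).
Reducing jointly to a common year set is what licenses the shared sampling
variance below; strata with n < 4 years or a constant variable are skipped.
Each correlation is Fisher-transformed, z = arctanh(r), after clamping
|r| ≤ 1 − 10⁻¹², which maps a perfect sample correlation to a large finite
effect size (|z| ≈ 14) instead of infinity while perturbing realistic r by
nothing measurable.

The sampling variance of each z is 1/(n − 3).  The three effect sizes of a
stratum are mutually dependent because every pair shares a variable; the
within-stratum 3×3 block uses the standard large-sample covariance for two
correlations r_ab, r_ac sharing variable a (Olkin–Siotani/Steiger):

    cov(z_ab, z_ac) = [ r_bc (1 − r_ab² − r_ac²)
                        − ½ r_ab r_ac (1 − r_ab² − r_ac² − r_bc²) ]
                      / [ (n − 3)(1 − r_ab²)(1 − r_ac²) ]

with role assignment per pair: (PT, PC) share phenology, (PT, CT) share
time, (PC, CT) share climate.  The formula is validated in the test suite
against a Monte-Carlo oracle (empirical covariance of Fisher-z pairs from
trivariate-normal samples).  Two accuracy facts worth knowing:

* it is a first-order (delta-method) result with an O(1/n) *relative*
  bias — roughly +8% at n = 10, +1.3% at n = 30, +0.7% at n = 50 for
  moderate correlations.  A simulation with enough replicates (≳10⁵) will
  resolve this bias; so will it resolve the analogous finite-n error of
  var(z) = 1/(n − 3) itself.  The tests therefore assert agreement at the
  approximation's order (3 MC SE + |cov|/n), and one full-scale check at
  10⁶ replicates documents the asymptotic bias explicitly;
* for extreme correlation triplets the assembled block can be slightly
  indefinite.  A guard shrinks the off-diagonals toward zero by the minimal
  common factor restoring positive semi-definiteness (bisection, 60 steps);
  the exact 1/(n − 3) diagonal is never modified, and the event is rare
  enough that a sweep of 10⁴ random valid triplets in the tests exercises
  it only at the PSD boundary.

## Trivariate mixed-effects meta-regression

Stacked model over m strata (k = 3m observations, fixed (PT, CT, PC) order
within stratum):

    z = W β + ε + u,   Var(z) = Ω(θ) = V + Σ_g Z_g (I ⊗ T_g) Z_gᵀ

V is the known block-diagonal within-stratum covariance assembled above.
Fixed effects use cell-means coding: each effect type, crossed with any
categorical moderators (taxon, trophic group, region …), has its own
column — no global intercept, so every coefficient *is* a group's mean
effect size, and "slope extraction" is a re-indexing.  Rank deficiency and
unresolvable moderator levels are design-time errors.

Each random grouping g (series start year, series end year, station nested
in region, or the stratum itself) carries a 3-dimensional deviation per
level with covariance T_g.  T_g is parameterized by its Cholesky factor
(guaranteeing PSD), or diagonal-only (`diagonal_random=True`, the default)
when the stratum count cannot identify cross-effect covariances.
Estimation maximizes the multivariate-normal likelihood over θ with β
profiled out by GLS at every evaluation; ML is the default, REML a flag.
The optimizer is L-BFGS-B with relative tolerance 10⁻⁸ and a configurable
number of perturbed restarts (default 5); non-convergence is a reported
state on the fit object, never a silent result or an exception.  When every
grouping distinguishes every stratum, Ω stays block diagonal and the
likelihood is evaluated with batched 3×3 Cholesky factorizations — this is
what makes the 500-replicate recovery experiment cheap; otherwise a dense
factorization is used.  With no random groupings the fit is plain GLS with
no optimization, which is also the closed form the tests compare against.

The implementation is validated two ways: against the dense GLS closed form
with variance components fixed (10⁻⁸), and against an independent
mixed-effects meta-regression implementation (metafor's `rma.mv`, run
through Rscript in one test) on an identical design — β, standard errors,
τ² and the log-likelihood agree to ~10⁻⁵.

Confidence intervals are Wald: estimate ± z₀.₉₇₅ × SE from the GLS
covariance at the ML variance components; a slope is *significant* iff its
95% CI excludes zero.  No multiplicity correction is applied.  Estimates
can be mapped to the correlation scale by tanh (monotone, so CI ordering
and significance are preserved).

## Tracking classification

Each stratum's (PT, CT, PC) triplet of (estimate, significant) pairs maps
to exactly one status:

| PT sig | CT sig | condition | status |
|---|---|---|---|
| yes | yes | PC sig and sign(PT) = sign(PC)·sign(CT) | tracking_shift |
| yes | — | otherwise | not_tracking |
| no | yes | — | stationary_changing_climate |
| no | no | — | tracking_stationary |

`tracking_shift` and `tracking_stationary` count as tracking; a stationary
phenology in a changing climate does not, and is kept as its own reporting
bucket.  Direction is advancing (significant PT < 0), delaying
(significant PT > 0), else none.  A significant estimate of exactly zero —
measure-zero in practice — fails the sign-consistency product and gets
direction none.  The classification is a pure function and is tested by
exhaustive enumeration of all sign × significance combinations against an
independently hand-coded table.

## Trend-diversity ellipses

Each trophic group's (PT, CT) slope pairs are summarized by a 95%
bivariate-normal ellipse: with sample mean μ̂ and covariance Σ̂, area =
π · q · √det(Σ̂), q = χ²₂(0.95) ≈ 5.991.  Area uncertainty comes from
conjugate normal–inverse-Wishart draws of the covariance, Σ ~
IW(ν₀ + n, Ψ₀ + S), with the weakly informative default ν₀ = d + 1 = 3 and
Ψ₀ = the sample covariance (both exposed).  Fewer than 3 points or a
collinear cloud is a degeneracy error.  By default the ellipse points are
the extracted per-stratum slopes; raw Fisher-z triplets can be supplied
instead.

Pairwise overlap is Monte-Carlo: uniform points over the bounding box of
the union, reported three ways — intersection/union (symmetric) and the
shared fraction of each ellipse — because "shared % of ellipse space" is
directionally ambiguous; a binomial standard error accompanies the
estimate.  10⁵ points resolve the third significant figure, which is why
exact conic intersection was not worth its complexity.  The MC estimate is
tested against the analytic circle-lens area for two unit circles.

## Comparison statistics

Downstream tests operate on slope/verdict tables: a factorial ANOVA with
type-II sums of squares (robust to the unbalanced stratum counts; full
interactions by default, main-effects only via a flag) on PC slopes; a
Brown–Forsythe (median-centred Levene) test on PT slopes — median centring
because slope distributions are heavy-tailed — with the mean-centred
variant behind a flag; Pearson chi-squared without continuity correction on
tracking contingency tables, warning when expected counts drop below 5; and
per-stratum abundance trends (Pearson r of annual mean abundance vs. year,
direction by the Fisher-z 95% CI) cross-tabulated against tracking status.
Degenerate inputs (constant abundance, single-cell tables, zero marginals)
are flagged or rejected rather than silently absorbed.

## Synthetic data: what it emulates, and what it does not

The generator produces the statistical structure the pipeline assumes:
monthly sampling over ≥10-year spans, a unimodal Gaussian-on-the-circle
seasonal curve per taxon (so winter-peaking taxa exercise the unwrap
logic), a linear drift b_PT (days/yr) in peak timing, climate covariates
with linear trends b_CT plus a sinusoidal seasonal cycle and Gaussian
noise, lognormal observation noise with zero-inflated detection, and a
taxon × station × region × estuary hierarchy over three trophic groups.
Phenology is forced by the *realized annual anomaly* of the driving
covariate (b_PC, days per unit), so the anomaly contains the climate trend
— intentionally reproducing the PT/PC collinearity the real analysis
faces.  Defaults describe one desk-scale estuary: 30 years, 2 regions × 2
stations, 4 taxa per trophic group, σ_season = 30 d (a strongly seasonal,
bloom-like curve), σ_obs = 0.3 (≈30% CV), σ_peak = 5 d, 5% detection
failure, b_PT = −0.5 d/yr.  The three presets differ only in which
covariate trend dominates and drives phenology: salinity in
"sanfrancisco-like" (drought-driven salinization), temperature in
"chesapeake-like" and "massbay-like".

The ground truth includes the implied asymptotic PT/CT/PC correlations,
derived by variance propagation treating year as uniform over the span and
including the annual-mean climate noise (σ_c²/12), the peak jitter, and
the mid-month quantization of the extracted peak date ((365.25/12)²/12,
a uniform-dither approximation).  Not emulated: population dynamics
(no predator–prey coupling or stock–recruitment), multimodal or
duration-changing seasonal shapes, temporally autocorrelated noise, gear
or program changes.  Passing end-to-end tests therefore demonstrate that
the chain of estimators recovers known trends under the model's own
assumptions — not that real monitoring data satisfy those assumptions.

`simulate_effect_sets` bypasses the series stage and draws effect-size
triplets directly for meta-model experiments: true stratum effects from
MVN(β, diag(τ²)), observations from MVN(true, Σᵢ).  By default Σᵢ is built
from the correlations implied by the *population* fixed effects tanh(β),
which keeps the GLS weights independent of the random effects and the
estimator exactly unbiased — the configuration used for the calibration
experiment (500 replicates at m = 200: bias within Monte-Carlo error, 95%
CI coverage ≈ 0.94–0.96).  The `sigma_from="stratum"` variant instead
builds Σᵢ from each stratum's own drawn correlations, mimicking the real
pipeline where blocks are estimated from observed correlations; this
induces a small weight–effect correlation bias (≈1–3% away from zero at
τ ≈ 0.2) worth knowing about when interpreting real fits, and is left as
an option rather than the calibration default.

## Numerical conventions, in one place

* Correlation clamp 1 − 10⁻¹² before arctanh; pairwise-complete reduction
  to one common year set per stratum; n ≥ 4 enforced everywhere 1/(n − 3)
  appears.
* PSD repair by off-diagonal shrinkage (never diagonal modification),
  triggered below −10⁻¹⁰ × trace.
* Optimizer: L-BFGS-B, ftol 10⁻⁸, ≤500 iterations, 5 restarts by default
  (1 in the bulk recovery experiment, where the profiled likelihood in 3
  diagonal variance parameters is well-behaved); variance parameters enter
  squared (diagonal) or via Cholesky (full), so PSD holds by construction.
* Ellipse coverage fixed at 0.95 (χ²₂ quantile); inverse-Wishart draws are
  seeded through `numpy.random.default_rng`; overlap MC uses 10⁵ points by
  default with the seed recorded on the result.
* Problem sizes in the shipped experiments (500 × m=200 recovery, 10⁶
  replicates per grid point in the covariance study, 50-seed end-to-end
  recovery) were chosen to bound each experiment's Monte-Carlo error well
  below the effect being measured while keeping the whole suite a
  few-minutes run on one core.

## Known limitations

* The meta-regression assumes independent effect-size triplets across
  strata given the random effects; spatial correlation between nearby
  stations beyond the station/region random effects is not modelled.
* No temporal autocorrelation in the yearly series; the Pearson/Fisher
  machinery treats years as exchangeable around the linear trend.
* The monthly resolution floors how small a drift is detectable; the
  mid-month convention quantizes peak dates to 12 values per year, an
  effective extra noise of ~8.8 days SD that the implied-correlation
  calculation accounts for but short series cannot overcome.
* Peak timing is the only phenological statistic: bloom duration, onset,
  and multimodal seasonality are out of scope.
* The covariance formula's finite-n bias (above) is inherited by the
  meta-regression's V; at the ≥10-year series lengths the filter enforces,
  the bias is ≤ ~8% of an already second-order quantity.
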