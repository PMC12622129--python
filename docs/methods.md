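# Methods

This package implements a patient-level forecasting analysis of geographic
atrophy (GA) lesion growth: hierarchical Bayesian fits of candidate growth
laws to longitudinal lesion-area series, rolling out-of-sample probabilistic
forecasts, proper-scoring-rule evaluation and model weighting, growth-phase
stratification, and a hierarchical Gamma meta-regression of forecast error.
Because real GA cohorts are access-restricted clinical data, a synthetic
cohort generator reproduces the statistical structure the analysis assumes;
all empirical statements below are about what the code computes on such
synthetic cohorts.

## Growth laws

Lesion area A(t) (mm², t in years since the eye's first visit) is modelled
by six mean functions:

| model | A(t) | bounded |
|---|---|---|
| Gompertz | K·exp(−b·e^(−ct)) | yes |
| logistic | K / (1 + e^(−r(t−t₀))) | yes |
| linear | max(0, a + s·t) | no |
| effective radius | max(0, a + s·t)² | no |
| von Bertalanffy | K·(1 − e^(−k(t−t₀)))³, clipped at 0 | yes |
| Mitscherlich | K·(1 − e^(−k(t−t₀))), clipped at 0 | yes |

The Gompertz displacement form (K, b, c) is used so the baseline area
K·e^(−b) can sit near zero, matching cohorts in which a quarter of eyes have
no measurable GA at the first visit.  The effective-radius law is the
field's square-root transformation: its likelihood applies to √area
(radius), and predictive draws are squared back so every model is scored in
mm².  Linear and effective-radius means are clipped at zero on the mean,
not the data.

Landmarks of a bounded trajectory are the time of maximum growth rate
(Gompertz: ln(b)/c, where the area equals K/e; logistic: t₀) and the two
inflections of the rate curve (A‴ = 0) that bracket it.  For the Gompertz
law these inflections solve u² − 3u + 1 = 0 with u = b·e^(−ct); the
implementation finds them numerically (bracketed root of a finite-difference
rate curvature, tolerance ~1e−8 y, search window [−5, 50] y) and the closed
forms serve as test oracles.  The Mitscherlich rate is monotone, so its
"peak" is the onset t₀ and it has no inflections.

## Hierarchical model and priors

Observed areas (or radii) are Gaussian about the eye's mean curve with one
shared noise sd σ.  Each transformed parameter (log K, log b, log c, …)
decomposes as population location + patient effect + eye-within-patient
effect, sampled non-centered (sparse per-eye series make the centered
geometry pathological; a centered option exists).  Priors are weakly
informative and scaled to the cohort: the asymptote prior is lognormal
centred near 10 mm² and truncated above at 4× the largest observed lesion
(prior-predictive areas stay in a plausible range), slopes/offsets get broad
normals, random-effect sds are half-normal(0.5) on transformed scales, and
σ is half-normal(1 mm²).  For model comparison, pointwise log-likelihoods
are always evaluated on the *area* scale; the radius-scale fit receives the
change-of-variables Jacobian 1/(2√a) (areas floored at 1e−6 mm²) so
PSIS-LOO compares densities of the same observable.

## Posterior computation

No probabilistic-programming framework is assumed; the package carries its
own Hamiltonian Monte Carlo engine (`gagrowth._sampler`) specialised to
these posteriors:

* every likelihood supplies an **analytic gradient** (verified against
  finite differences), vectorized across chains;
* chains start at the posterior mode, found by L-BFGS-B and polished by
  damped-Newton steps — the batched finite-difference Hessian costs two
  vectorized gradient calls, and quasi-Newton line searches alone stall in
  this stiff geometry (curvature conditioning ~1e5);
* the kinetic metric is the curvature-informed *diagonal* of that Hessian.
  A full inverse-Hessian metric was tried and rejected: its frozen
  correlations destabilise trajectories once chains leave the mode region
  of the hierarchical funnel;
* the residual soft mode (a population mean trading off against the summed
  random effects) is handled by lengthening trajectories to the softest
  standardized mode's scale (estimated from the Hessian spectrum, capped),
  with randomized path lengths to avoid periodic-orbit resonance;
* step size adapts by dual averaging to ~0.8 acceptance; divergent
  transitions are counted and a rate above 2% attaches a warning to the
  fit (results are still returned for inspection).

Defaults are 4 chains × 500 warmup + 400 kept draws.  On simulation-based
calibration runs at the scale used in the tests (30 eyes × 8 visits,
σ = 0.3 mm², 20 replicates) the population log-asymptote and log-rate 90%
credible intervals cover the generating values in 17/20 and 19–20/20
replicates with ≤4% relative bias of posterior medians.  Mixing is
deliberately budget-bound: population-location ESS is in the tens-to-
hundreds per fit at these settings, and the weakly identified asymptote
random-effect sds mix slowest; the analysis scripts report per-fit R-hat
and ESS so longer runs can be requested (`--warmup/--draws`).  Convergence
thresholds default to R-hat ≤ 1.01 and ESS ≥ 400 and are configurable; a
full-scale scientific run would use stricter values (R-hat < 1.001,
ESS > 1000) with correspondingly longer chains.

## Synthetic cohorts

The generator (`gagrowth.simulate`) emulates a single-centre natural-history
clinic population:

* 121 patients by default; a second eye with probability 0.496;
* per-parameter Gaussian patient and eye effects on transformed scales, with
  defaults (log K ~ log 10 ± 0.5/0.35, log b ~ log 2.5 ± 0.35/0.25,
  log c ~ log 0.45 ± 0.25/0.15 for patient/eye levels) chosen so the median
  baseline area is ≈0.8 mm², peak growth falls near year 2, and
  deceleration begins around year 4 — i.e. typical follow-up spans all
  growth phases;
* visit counts are a shifted negative binomial floored at 5 (median ≈7,
  IQR ≈4); the schedule is a six-month scheduled grid with skipped
  appointments (each scheduled slot attended with probability 0.6, plus
  Gaussian jitter, gaps floored at 0.1 y).  The thinning is what reconciles
  six-month imaging with a ~5.5-year median follow-up at seven visits —
  a strictly six-monthly schedule cannot produce both;
* observation noise is Gaussian truncated at zero, default σ = 0.3 mm²,
  aligned with the inference default rather than a lognormal error; the
  real measurement-noise magnitude is unknown, so σ is a free knob, not an
  estimate of any instrument's error;
* each eye is re-drawn (deterministic derived streams, bounded retries)
  until it passes the default inclusion filters, so the emitted cohort
  survives filtering unchanged.  This conditions the truth distribution
  slightly toward faster-growing eyes, which mirrors the real cohort's
  inclusion conditioning;
* all randomness descends from one seed through `SeedSequence` spawning, so
  per-patient streams are order-independent.

What the generator does **not** emulate: segmentation error structure
(spatially correlated, size-dependent), multifocal and satellite lesions,
informative visit timing (sicker patients returning sooner), censoring by
death or treatment switch, and between-eye correlation beyond shared
patient-level growth parameters.  Tests passing on these cohorts therefore
establish the statistical machinery's correctness and the qualitative
model-comparison behavior, not clinical performance on real FAF series.

## Cohort handling

Input tables carry patient id, eye id, visit date (converted to years since
the eye's first visit at day-count/365.25) or t directly, lesion area in
mm², and a gradability flag (absent column → all gradable; image QC itself
is upstream and out of scope).  Duplicate timestamps keep the last record
with a warning.  The inclusion rule keeps eyes with ≥5 gradable visits of
which ≥3 show area strictly >2 mm² (non-gradable visits are dropped before
counting); filtering is idempotent and the report's counts balance.  The
trial-eligibility annotation marks visits with area in the closed interval
[2.5, 17.5] mm².

## Forecast validation

From each eye's fifth visit, the harness refits the model on the focal
eye's truncated history plus every other eye's complete history (population
parameters stay informed; only the focal eye is truncated) and predicts the
next visit — one-step-ahead with growing history, the default `next`
scheme.  The phrasing "predict each subsequent visit from the fifth" also
admits a fixed-origin reading, exposed as `scheme="all-from-5"`.  A leakage
assertion verifies the focal eye's future never enters a training set.
Failed refits are flagged, excluded from scoring, and counted.

Scores per forecast: sample CRPS with the unbiased S(S−1) pairwise term
(computed by an O(S log S) sorted-sum identity, exact for small draw
counts), absolute error of the predictive median, and 90% equal-tailed
interval width/coverage with type-7 interpolated quantiles (stated so
results are bit-reproducible).  Cohort-level CRPS/MAE are unweighted means
over tasks.  Model weights are pseudo-BMA+: PSIS-LOO pointwise elpds
(generalized-Pareto tail smoothing via arviz, Pareto-k diagnostics
reported), Bayesian-bootstrap Dirichlet(1) replicates over observations,
per-replicate softmax, replicate-averaged weights.  Degenerate all-equal
log-likelihood columns reduce to uniform weights rather than erroring.

## Phase stratification

Forecast windows are labelled acceleration (before t_accel), linear
([t_accel, t_decel], closed so boundary ties are not "mixed"), deceleration
(after t_decel), or mixed (window straddles a boundary).  Landmarks come
from a single reference Gompertz fit per eye (posterior-median parameters);
in simulation studies the truth landmarks are selectable — using one
reference fit rather than each candidate's own landmarks keeps strata
comparable across models, at the cost of tying the stratification to the
reference law.  Per-(phase, model) tables report mean CRPS, a 95% bootstrap
interval over tasks, and the probability of being best (share of bootstrap
replicates with the lowest stratum mean; exact ties share credit).

## Meta-regression of forecast error

Per-forecast CRPS is Gamma-distributed with a log link, parameterized by
shape α (lognormal prior) and mean exp(η); η has a fixed intercept per
model, model-specific slopes for standardized horizon and standardized
prior-visit count (one global SD each, computed from the analysis sample),
and non-centered patient and eye random intercepts.  CRPS values below
1e−6 mm² are floored there (Gamma support excludes zero; this arises only
in degenerate noiseless tests).  Marginal effects are exp(β·δ)−1 per δ SDs,
reported as percent; the probability of being best evaluates each draw's
expected CRPS at reference covariates (0 SD, random effects at the
population level — "a new forecast") and counts strictly-lowest draws,
splitting ties.

## Problem sizes

The test-suite and acceptance-script runs use desk-scale problems chosen as
this package's own defaults: parameter recovery at 30 eyes × 8 visits × 20
replicates; model-selection operating characteristics on ~14-eye cohorts
over 5 seeds per generating law; rolling forecasts on a ~9-eye cohort
(~30 tasks, every task a full refit); meta-regression recovery at ~45 eyes
(~540 records) × 10 replicates.  The analysis scripts default to larger
cohorts and expose `--max-eyes`, `--warmup`, `--draws` to scale up.

## Known limitations

* The sampler trades tail ESS for wall-clock time at default settings; the
  divergence counter and R-hat/ESS report are the guard rails.
* The Gaussian observation model is a convention, not a validated error
  model for FAF segmentation; the truncation at zero is applied to draws,
  not the likelihood.
* Pseudo-BMA+ weights describe relative predictive support; they are
  reported, not used to blend forecasts.
* With one reference fit per eye, phase labels inherit that fit's
  uncertainty; labels from posterior-median parameters carry no error bars.
* The synthetic generator's rejection step conditions the truth
  distribution on passing inclusion; population-level "truth" values in
  recovery tests refer to the pre-rejection generating laws, which is why
  recovery tolerances are stated in coverage terms rather than exact
  equality.
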