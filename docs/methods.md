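# Methods

This note records the model, the numerical choices, and the design
decisions behind `harvestipm`, at the level of detail a maintainer or a
reviewer of results produced with it would want.

## Population model and timeline

The latent state is January abundance `N[t, a, s]` for years `t = 1..T`,
ages `a = 0..A` (cubs at age 0; the terminal class `A+` accumulates all
older animals) and two sexes. The annual cycle follows the bear life
history that motivates the model: animals suffer all non-hunting
mortality of the year before the autumn hunt; the hunt removes a
fraction `H[t, a, s]` of the survivors; essentially no mortality occurs
between the hunt and the January birth pulse (bears den through that
window), so hunt survivors pass intact into the next age class.
Cubs are not legally harvested: age 0 transitions to age 1 with fixed
sex-specific cub survival, and age-1 animals face their first hunt
after yearling (den-emergence-to-autumn) survival.

Consequences used by tests and by the estimation design:

* conservation through the hunt is exact:
  `N·S = Ĉ + (next year's entry)` for every harvestable class;
* recruitment and cub survival enter predictions only through their
  product, so they are not separately estimable from harvest data —
  scaling `R_t` by `c` and cub survival by `1/c` leaves every predicted
  harvest unchanged, exactly. The model therefore fixes cub survival
  (0.88 female, 0.76 male, values from den-check studies of the source
  system) and male yearling survival (0.88), and estimates female
  yearling survival through a difference transform
  `S_f1 = S_m1 + (1 − S_m1)·logistic(θ)` that enforces the biological
  constraint `S_f1 ≥ S_m1`. Non-hunting survival of ages 2+ is constant
  over age and time, one parameter per sex.

λ_t = N_{t+1}/N_t is computed excluding cubs by default, matching the
scale of the mark-recapture estimates (which exclude cubs); a flag
includes them.

## Harvest vulnerability

`H = 1 − exp(−exp(η))` with an additive linear predictor on the
complementary log-log scale: a natural cubic spline in age (3 df,
interior knots at ages 2 and 7 — flexibility at early ages and an
inflection after maturity — and boundary knots at 1 and 10), a male
offset (females are the reference), and a temporal block. The basis is
the truncated-power natural-spline construction without an intercept
column; the intercept lives in the temporal block, which keeps the
parameterization identifiable. Ages at or beyond the boundary knot
(the plus-group is evaluated at its nominal age A) use the linear
extrapolation the natural constraint forces. The linear predictor is
clipped at |η| = 38 so rates are strictly inside (0, 1) for any finite
parameters.

Temporal variants:

* `fe`: `intercept + β_food·f_t + β_effort·e_t`, with the covariates on
  their native index scale (matching the axis conventions of the
  telemetry analyses; a centering flag is not needed because the
  intercept absorbs the level). Years in the leading block without
  covariates get one free effect each, used *instead of* the intercept
  and covariate terms — hence 3 + 4 = 7 temporal parameters for a
  series with 4 covariate-missing years.
* `yr`: one free effect per year (T parameters). Covariate inputs are
  ignored (logged at debug level).

## Estimation

All estimated quantities are mapped to an unconstrained vector: log
initial abundances (ages 1..A by sex), log cub recruitment for years
1..T−1 (the final year's cubs never reach harvestable age within the
data span; they are pinned to the previous year's value), the survival
transforms, and the harvest block. For the 29-year, 10-age, two-sex
configuration this gives 62 (`fe`) or 84 (`yr`) parameters against 580
observation cells.

The objective is `Λ = Σ (O − E)²/max(E, ε) + w·Σ ((N̂_t − N_t)/SE_t)²`
with ε = 1e-8 guarding cells whose predicted harvest is essentially
zero (old male classes late in a declining cohort can predict ~0 while
observing 0; without the floor those cells would dominate). Both terms
are sums of squares, so the minimizer is `scipy.optimize.least_squares`
(trust-region reflective, a Gauss-Newton-family quasi-Newton method)
on the residual vector, with:

* a batched central-difference Jacobian (relative step 1e-6; all
  perturbed parameter vectors are evaluated through one vectorized
  projection, so a Jacobian costs about as much as a handful of
  objective evaluations);
* `x_scale='jac'` — the problem is badly scaled (Hessian eigenvalues
  span ~0.4 to ~3e7 at typical optima) and adaptive column scaling is
  what makes trust-region steps reliable here;
* a generous box of ±25 on every unconstrained coordinate. The box
  never binds at plausible optima (log-abundance 25 ≈ 7e10 animals); it
  exists to keep far-flung trial points inside the numerically safe
  region of the exponentials.

Multi-start: the first start is data-informed — initial abundances from
per-sex Downing reconstructions scaled ×1.5 (the reconstruction counts
only the eventually harvested segment), recruitment at twice each
year's total harvest, survivals at 0.85, harvest coefficients at zero
with temporal levels near cloglog(0.12) — and subsequent starts (5 by
default) add N(0, 0.2) jitter. By default the sequence stops as soon
as a start satisfies both convergence diagnostics; with early stopping
disabled the best objective over all starts is retained (near-ties go
to a converged start). Non-convergence is reported in the result, never
raised.

Convergence is declared when (i) the scaled gradient max-norm
`max_i |g_i|·max(1, |θ_i|) / max(1, Λ)` is below 1e-4, with the
gradient from batched central differences, and (ii) the
finite-difference Hessian of Λ (full second-difference stencil,
relative step 3e-4 — chosen for second-derivative accuracy; coarser
steps visibly contaminate the small eigenvalues with truncation error)
is positive definite. Positive definiteness is determined with a
numerical-noise floor: an eigenvalue is treated as negative only if it
is below −64·eps·‖H‖. Weakly identified directions (terminal-year
recruitment, early free year effects) produce true eigenvalues many
orders of magnitude below the largest, and a finite-difference Hessian
cannot distinguish such an eigenvalue from zero; without the floor the
diagnostic rejects optima for curvature of −1e-13 against a norm of
1e7, which is floating-point noise, not a saddle.

At the optimum of a well-specified fit, the chi-square component is
comparable to a χ²(n − p) variable; the test suite checks that the
objective evaluated at the true generating parameters over repeated
noisy datasets averages within 10% of n − p.

## Data corrections

Sex misclassification is corrected at the (year × age) cell level — not
on year totals — to preserve age-specific sex structure, by inverting
the 2×2 forward map built from telemetry rates (misclassified females /
female sample, misclassified males / male sample). The solve conserves
each cell total; corrected counts are kept as reals (the chi-square
objective accepts non-integer observations, and re-rounding would bias
small cells). Cells whose solution goes negative (possible at extreme
sex ratios) are clipped to zero with the total preserved, and counted
in a warning. Aged-fraction inflation divides each year by its aged
fraction, leaving within-year age/sex proportions untouched. The
pipeline applies misclassification correction first and inflation
second, matching the order of the bootstrap resampling steps.
Plus-group pooling sums ages ≥ cutoff and drops (and logs) illegal cub
records.

## Downing reconstruction

Ages are collapsed to 1, 2, 3+ (the recommended configuration for this
kind of data) and reconstructed backwards: terminal year
`N[T, a] = C[T, a]`; younger classes `N[t, a] = C[t, a] + N[t+1, a+1]`;
pooled class `N[t, P] = C[t, P] + N[t+1, P] − (N[t, P−1] − C[t, P−1])`,
so survivors of the class below the pool are not double-counted. This
recursion is algebraically identical to crediting each pooled harvest
with the minimal possible age (exactly the collapse age) and counting
every harvested animal alive in all prior years back to class 1 — the
cohort-accounting oracle the tests validate against. Reconstructed
yearly totals are exact for the harvested segment when no animal
survives a calendar year inside the pool; otherwise pool-resident years
are missed, which is why the method tracks trend, not absolute
abundance, and why its terminal years (incomplete cohorts) are
unreliable. Negative pooled values (inconsistent data) are clamped to
zero with a warning. Combined-sex mode sums the male and female
matrices before reconstructing.

## Bootstrap

For each replicate: (1) aged-harvest records are resampled with
replacement within each year (a multinomial over that year's
(age, sex) cells at the year's aged sample size); (2) the telemetry
misclassification counts are binomially resampled at their sample
sizes; (3) the replicate's correction factors and the fixed per-year
aged fractions are re-applied; (4) mark-recapture estimates are drawn
from Normal(point, SE). The model is refit to each replicate and
pointwise percentile intervals are taken over converged replicates.
Dropped (non-convergent) replicates are counted and reported, with a
warning above 10%. The intervals describe how the estimates would vary
under replication of the data-collection process; they do not account
for error in the process model itself.

## Simulation framework

The operating model runs the same timeline with integer states and
binomial demographic stochasticity: survivors ~ Binomial(N, S) before
the hunt, harvest ~ Binomial(survivors, H), cub-to-yearling survival
binomial as well. Recruitment is a constant 4,400 cubs per year in the
Baseline. Baseline harvest rates use the covariate sub-model with
telemetry-style coefficients — a linearly decreasing age effect (slope
−0.08 per year of age on the cloglog scale), male offset +0.35, food
coefficient −0.12, effort coefficient +0.12, intercept −1.492 (about a
14% female rate at age 5 with both indices at 6.5). The covariate
series are stationary, centred at 6.5, drawn once from an internal
fixed seed so they are identical across replicates (per-replicate
randomness is confined to the demographic and observation draws); the
4 leading years are flagged unavailable to the estimator. The initial
population is the deterministic equilibrium age structure scaled to
45% — the trajectory then rises for roughly its first 15 years and
levels off, with mean abundance (cubs excluded) near 14 thousand.
Mark-recapture estimates are generated in 1991, 1997 and 2002 with an
8% CV (SE set to exactly 0.08 × truth; the estimate drawn Normal).

Scenario modifiers, all zero in the Baseline and all config-exposed
(defaults chosen as plausible magnitudes for this system, since only
the qualitative descriptions of the deviations are fixed):

| scenario | modifier | default |
|---|---|---|
| StochasticRates | i.i.d. normal year effects on cloglog(H) and logit(S) | sd 0.2 |
| TrendsInHarvest | linear drift of the harvest intercept over the series | 0.5 total |
| IncreasingS | linear increase of non-hunting survival | +0.04 total |
| ReportingError | binomial underreporting of age-1 harvests | 20% |
| IncorrectSurvival | shift of the cub/yearling survivals the estimator fixes | −0.05 |
| FoodSexEffect | extra food coefficient for females | −0.05 |
| KitchenSink | all of the above | — |

Estimation models in the experiment always keep the fixed survival
constants even when the operating model deviates — that mismatch is the
point of IncorrectSurvival and KitchenSink. Replicate seeds are spawned
deterministically from the experiment master seed and recorded.

What the generator does *not* emulate: ageing error in cementum annuli,
spatial heterogeneity, immigration/emigration, density dependence,
individual heterogeneity in vulnerability, and non-representative aged
subsamples beyond the yearling-underreporting mechanism. Tests passing
on these simulations show the estimation machinery is correct and
robust to the listed misspecifications, not that the model is adequate
for any particular real dataset.

Evaluation metrics: mean abundance (cubs excluded, averaged over years
and replicates) for scale; λ_t = N_{t+1}/N_t and
MSE(λ̂) = mean over years and replicates of (λ̂_t − λ_t)², reported
×1000, for trend; plus pooled 2.5/50/97.5 percentiles of log λ̂.

## Problem sizes

The full study protocol uses 1000 replicates per scenario. The bundled
test suite runs the shared Baseline comparison and the acceptance
script at 100 replicates; the comparisons they support (convergence
fraction, estimator ranking by MSE, penalty-vs-bias ordering) are
decisively resolved at that size — the two Baseline biases being
compared are each below 1% of true abundance, so materially smaller
replicate counts leave their ordering dominated by Monte-Carlo noise.
The chi-square calibration check uses 200 datasets (objective
evaluation only, no fitting).

## Known limitations

* The initial age structure is one free log-abundance per (age, sex)
  cell — aggressive relative to the information in the data; a
  lower-dimensional parameterization (total + shape) would trade bias
  for stability.
* The `yr` sub-model's final-year effects are informed only by the
  final year's harvest and can be unstable; the mark-recapture penalty
  mitigates this.
* Bootstrap intervals are variability bands, not full uncertainty
  intervals (no process-model error).
* Downing reconstruction values are not abundance estimates; only
  their trend is meaningful, and the last few years are incomplete.
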