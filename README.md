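# harvestipm

Integrated age-at-harvest population modelling for harvested wildlife,
developed around the monitoring problem of black bears (*Ursus
americanus*): estimate abundance and population trend from the data a
management agency actually has — sex-specific age-at-harvest matrices,
annual indices of natural food supply and hunting effort, and a handful
of expensive mark-recapture abundance estimates — rather than from
continuous direct surveys.

The package is aimed at quantitative wildlife biologists and
biometricians. It provides:

* an age/sex-structured projection model fitted to age-at-harvest
  matrices by penalized chi-square minimization;
* the **Downing reconstruction** baseline (backward virtual-population
  accounting with collapsed older ages);
* a percentile **bootstrap** over the whole data-preparation pipeline;
* an **operating-model simulation framework** (eight scenarios with
  binomial demographic stochasticity) for testing estimator robustness
  under model misspecification;
* a CLI (`harvestipm`) with `fit`, `downing`, `simulate`, `experiment`,
  `bootstrap` and `make-fixtures` subcommands.

## The model

January abundance `N[t, a, s]` (age `a = 0..A` with cubs at 0 and a
terminal plus-group `A+`, sex `s`) evolves by: non-hunting survival
`S[a, s]` acting before the autumn hunt, harvest of the survivors with
finite probability `H[t, a, s]`, no mortality between the hunt and the
January birth pulse, and a recruitment `R_t` of cubs split evenly by
sex:

```
Ĉ[t,a,s]    = N[t,a,s] · S[a,s] · H[t,a,s]            (predicted harvest, a ≥ 1)
N[t+1,a+1,s] = N[t,a,s] · S[a,s] · (1 − H[t,a,s])      (a+1 capped at A+)
N[t+1,0,s]   = R_{t+1} / 2
```

Harvest vulnerability is a regression on the complementary log-log
scale with additive age, sex and temporal effects; the age effect is a
natural cubic spline (3 df, interior knots at ages 2 and 7, boundary
knots at 1 and 10). Two temporal sub-models are available: `fe`
regresses on the food and effort indices (7 temporal parameters when
the 4 leading years lack covariates) and `yr` estimates one free effect
per year (29 parameters for a 29-year series).

Fitting minimizes

```
Λ = Σ_{t,a,s} (C_obs − Ĉ)² / Ĉ   +   w · Σ_t ((N̂_t − N_t)/SE_t)²
```

where the penalty compares model abundance (cubs excluded) with
mark-recapture point estimates; `w = 0` ignores them, `w = 1` weights
them as one extra squared residual each, and large `w` (e.g. 200) makes
the fit track them closely. A fit is declared converged when the scaled
gradient vanishes and the finite-difference Hessian at the optimum is
positive definite; Λ's chi-square component is then comparable to a
χ²(n − p) variable with `n = 2·T·A` cells (580 for 2 sexes × 29 years ×
10 ages) and `p` estimated parameters (62 for `fe`, 84 for `yr`).

Raw registration data are corrected before fitting: reported sex is
de-biased with misclassification rates from telemetered harvested
animals (a 2×2 linear solve per year × age cell), counts are inflated
for the fraction of the harvest that was actually aged, ages above the
cutoff are pooled into the plus-group, and illegal cub records are
dropped.

## Worked example

Generate a fully synthetic, Minnesota-shaped input bundle and fit the
covariate sub-model with `w = 1`:

```
$ harvestipm make-fixtures --seed 5 --out fx
$ harvestipm fit --harvest fx/aged_harvest.csv --covariates fx/covariates.csv \
    --mr fx/mr.csv --misclass fx/misclassification.json \
    --aged-fractions fx/aged_fractions.csv --submodel fe --weight 1 --out fx/run
objective 892.71 (chi2 890.28 + penalty 2.43), converged=True
```

The objective (893 over 580 cells and 62 parameters) is the chi-square
discrepancy plus the mark-recapture penalty. `fx/run/fit.json` holds
the fitted harvest regression — here `beta_food = -0.120`,
`beta_effort = 0.117`, `sex_offset = 0.285`: harvest rates fall when
natural food is abundant, rise with hunting effort, and are higher for
males, recovering the coefficients the generator used (−0.12, +0.12,
0.35). `fx/run/trajectory.csv` contains the estimated abundance; this
run rises from ≈7,000 (excluding cubs) in 1980 to a plateau of
≈14,300 by the mid-1990s.

A small simulation experiment comparing estimators on the Baseline
scenario:

```
$ harvestipm experiment --scenario Baseline --reps 5 --seed 7 \
    --estimators fe-w1,fe-w0,downing-combined --out fx/exp
scenario        estimator  convergence_fraction  mean_true  mean_estimated  mse_lambda_x1000
Baseline          fe-w1.0                   1.0    14134.7         14372.3             0.034
Baseline          fe-w0.0                   1.0    14134.7         15237.8             0.049
Baseline downing-combined                   1.0    14134.7          5160.5            14.643
```

(abbreviated columns). Including the mark-recapture penalty (`w = 1`)
gives the least biased mean abundance, and both integrated estimators
track annual growth rates two orders of magnitude more accurately than
the Downing reconstruction, which recovers only the eventually
harvested segment of the population.

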