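# Methods

## Data-generating model

All simulated trials follow one causal ordering
`Z, U, L1, L2, A, Y`:

```
Z  ~ Bernoulli(0.5)                                  randomization
U  ~ Uniform(0,1)  (S1)  or  Bernoulli(0.5)          unmeasured confounder
L1 ~ Normal(lambda0 + lambda1*U, sigma)              continuous measured confounder
L2 ~ Bernoulli(expit(b0 + bU*U + bL1*L1))            binary measured confounder
A  ~ Bernoulli(g(alpha0(arm) + alpha1*Z + alpha2*L1 + alpha3*L2 + alpha4*U))
Y  ~ Bernoulli(g(theta0 + theta1*A + theta2*L1 + theta3*L2 + theta4*U + theta5*Z))
```

In setting `S1`, `g` is the inverse logit; the treatment-model "logit"
notation is read as the inverse-logit transform, the only
interpretation that yields valid Bernoulli parameters and reproduces
the designed nonadherence rates. In `S2`, `S3`, `A1`, `A2` the models
are linear in probability (`g` = identity), so `theta1` *is* the
marginal risk difference. The simplified settings `A1`/`A2` drop `L1`
and `L2` entirely.

Setting-level constants:

| setting | U | L1 | L2 model | links | structure |
|---|---|---|---|---|---|
| S1 | Unif(0,1) | N(6U, 2) | expit(-5 + 3U + 1.25 L1) | logistic | null effect; L sufficient |
| S2 | Bern(0.5) | N(3, 0.5) | expit(-3.5 + 0.6 L1) | linear | unmeasured confounding (theta4) |
| S3 | Bern(0.5) | N(3 + 0.05U, 0.5) | expit(-3.5 + 0.6 L1 + 0.1 U) | linear | direct Z->Y effect (theta5) |
| A1/A2 | Bern(0.5) | — | — | linear | no measured covariates |

In the `S3` treatment model the covariate terms are
`alpha2*L1 + alpha3*L2`, following the common template shared by all
settings and the registry's column layout (a transcription in one
source writes `L1` twice; the registry stores the coefficients by
column meaning).

The scenario registry (`src/adheresim/data/*.tsv`, one row per
scenario-arm) fixes arm-specific intercepts `alpha0` so per-arm
nonadherence hits designed levels of 10–90% (a handful of rows are
printed as 11/21/41/61/81/89/91% and are stored verbatim). Registry
sizes: 12 (S1), 60 (S2), 24 (S3), 60 (A1), 24 (A2). For `A1`/`A2`, no
tabulated intercepts exist, so they are solved exactly from the target
rate `r` under the linear treatment model:
`alpha0_treat = 1 - r - alpha1 - alpha4/2` and
`alpha0_control = r - alpha4/2` with `alpha1 = alpha4 = 0.1`,
`theta0 = 0.2`; scenario ordering follows the same block pattern as the
tabulated settings (treatment effect x confounding strength for `A1`;
confounding x violation severity for `A2`).

The evaluation truth `true_rd` is 0 for every `S1` scenario (the
outcome model has no `A` term) and `theta1` for the linear-link
settings, where the outcome model is linear in `A` and the RD is
collapsible.

**Clamping.** Gaussian tails of `L1` can push a linear-link probability
slightly outside [0, 1]. The predictor is clamped to [0, 1] before the
Bernoulli draw; clamp events are counted per trial and a `ClampWarning`
is raised when more than 5% of subjects were clamped (registry
scenarios stay far below this level; the guard exists for user-supplied
parameterizations).

**Random numbers.** Each replicate draws from an independent PCG64
stream keyed on `(master_seed, setting, scenario, replicate)` via
`numpy.random.SeedSequence`, so sweeps are reproducible replicate by
replicate and parallel execution is bit-identical to serial.

## Estimators

All point estimators fit the binary outcome with a Gaussian-family
identity-link linear model (ordinary or weighted least squares), so the
coefficient of interest estimates the risk difference directly, with a
heteroskedasticity-robust sandwich covariance. The robust variant is
HC0 — the plain sandwich `(X'X)^-1 X' diag(e^2) X (X'X)^-1` — with
HC1/HC3 selectable (`cov_type=`); confidence intervals are Wald with
the 1.96 normal quantile.

* **ITT**: `Y ~ Z`, all subjects. **Naive PP**: `Y ~ Z` restricted to
  `Z == A`. **Naive AT**: `Y ~ A`, all subjects.
* **Baseline-adjusted ITT/PP**: add `L1, L2` to the regression.
* **IP-weighted PP**: on the adherent subset, a logistic model
  `A ~ L1 + L2` gives `P_A`; stabilized weights
  `W = Pr(A=1) * A / P_A + Pr(A=0) * (1-A) / (1-P_A)` with the marginal
  `Pr(A=1)` taken as the subset sample proportion (the population
  entering the weighted model); then weighted LS of `Y ~ Z` with the
  weighted sandwich. A fitted `P_A` of numerically 0 or 1 marks the
  replicate non-converged.
* **2SLS (naive / first / both)**: logistic first stage `A ~ Z (+ L)`;
  second stage `Y ~ Ahat (+ L)`; the RD is the coefficient on `Ahat`.
* **2SRI (naive / first / both)**: same first stage; second stage
  `Y ~ A + (A - Ahat) (+ L)`; the RD is the coefficient on `A`. With a
  binary instrument and no covariates, 2SLS and 2SRI coincide exactly
  with the Wald ratio of arm differences.

Two-stage standard errors are the second-stage robust standard errors
with no correction for first-stage estimation uncertainty — a known
limitation of this presentation of the two-stage estimators, kept
deliberately so the uncertainty statements match the procedure being
studied.

The logistic first stages use Newton's method with a BFGS fallback.
One-sided nonadherence (a structural zero cell, as in a trial whose
control arm has no access to treatment) drives an intercept toward
minus infinity; BFGS converges the *fitted probabilities* to the cell
proportions, which is all the second stage consumes. Complete
separation — the fitted model reproduces `A` exactly, e.g. perfect
adherence — is reported as non-convergence, as is any rank-deficient
second stage.

**Nonparametric causal bound.** From the arm-wise empirical joint
probabilities `p_{ya.z}`, the bound is the maximum of eight lower and
the minimum of eight upper linear expressions. The expressions were
derived by enumerating the optimal dual solutions of the
principal-stratum linear program (16 response-type frequencies,
matched to the 8 observed probabilities, optimizing
`E[Y(1)] - E[Y(0)]`), and the test suite proves equality to a direct
`scipy.optimize.linprog` oracle over 10^4 random valid probability
configurations to 1e-9. Under perfect adherence the bound collapses to
the ITT risk difference.

## Monte-Carlo metrics

Over converged replicates `b_1..b_m` with truth `beta`:
`bias = mean(b) - beta`; `se = SD(b)` with divisor `m - 1`;
`mse = mean((b - beta)^2)` with divisor `m`;
`coverage` counts intervals with `ci_lower <= beta <= ci_upper`. The
divisors are kept asymmetric on purpose, so the identity
`mse = bias^2 + se^2 (m-1)/m` holds exactly and is enforced by a
property test. Non-converged replicates are excluded from all four
measures but reported (`n_sim` vs `n_converged`); a summary with fewer
than two converged replicates is flagged undefined rather than
invented. Bound summaries report the mean lower/upper bound and the
fraction of replicates whose bound contains the truth.

## Problem sizes and test design

The package's design scale is n = 2000 subjects (~1000 per arm) with
1000 replicates per scenario, and a sensitivity scale of n = 500. The
acceptance script runs the design scale (~3 minutes on one CPU). The
test suite uses 200 replicates for adherence calibration and 300–400
replicates for estimator-behaviour checks, with stochastic assertions
set at the expected level plus three Monte-Carlo standard errors of the
replicate mean, so tolerances scale with the replicate count actually
run. Oracle tests (sandwich matrix arithmetic, independent likelihood
optimization for the weights, the IV moment solution, the LP bound) are
deterministic.

## What the generator does and does not emulate

The generator reproduces the designed trial shapes: two arms,
randomization exactly Bernoulli(0.5), roughly equal per-arm
nonadherence (or one-sided when scenarios are customized), binary
outcome, and confounding structures spanning "measured covariates
sufficient", "unmeasured confounding", and "exclusion-restriction
violation". It does not emulate loss to follow-up or censoring,
time-varying treatment, multi-arm designs, cluster randomization,
measurement error, or covariate-dependent randomization. Passing tests
therefore certify estimator behaviour under point-treatment
nonadherence with baseline confounding only; real trials with follow-up
dropout or sustained treatment strategies need different machinery.

## Known limitations

* Two-stage standard errors ignore first-stage uncertainty (see above).
* The NPCB is computed on empirical probabilities; no sampling
  uncertainty is attached to the bound ends (they are bounds, not
  confidence intervals).
* Estimates at >90% nonadherence or tiny samples (n ~ 100) frequently
  fail to converge; the harness records rather than repairs this.
* No multiple-testing adjustment anywhere: the pipeline reports one
  estimand per method.
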