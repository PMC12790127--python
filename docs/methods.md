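# Methods

This document describes the statistical models, the synthetic
data-generating process, and the numerical choices made in `frailcurve`.

## 1. Notation and setting

Subjects `i = 1..n` are nested in operators (physicians) `j = 1..J`, which
are nested in centers. Each subject has an observed follow-up time `T_i`
(days), an event indicator `delta_i`, covariates `x_i`, and a case order
`n_i` — the position of the procedure in its operator's personal case
sequence (1 = first case). "Success" at a horizon `t*` means surviving
event-free to `t*`; the default horizon is 30 days.

## 2. Shared gamma-frailty Cox model

The hazard for subject `i` in cluster `j` is

```
h_ij(t) = h0(t) * w_j * exp(beta' x_ij)
```

with `w_j ~ Gamma(1/theta, theta)` i.i.d., so `E[w_j] = 1` and
`Var[w_j] = theta`. `theta = 0` recovers the ordinary Cox model.

### EM algorithm

The model is fit by expectation-maximisation on the complete-data
likelihood, with the frailty variance profiled out:

* **E-step.** Given the current `beta` and the Breslow baseline, the
  posterior frailty mean for cluster `j` is

  ```
  w_j = (1/theta + D_j) / (1/theta + H_j)
  ```

  where `D_j` is the cluster's event count and
  `H_j = sum_i Lambda0(T_i) exp(beta' x_i)` its accumulated cumulative
  hazard (excluding the frailty itself).

* **M-step.** A Cox partial-likelihood fit with `log w_j` entering the
  linear predictor as a fixed per-subject *offset*, followed by a Breslow
  baseline update. General-purpose Cox implementations do not expose
  offsets, which is why the package carries its own compact Newton solver
  (`frailcurve._cox_core`); it is cross-checked against lifelines in the
  test suite (agreement to ~1e-6 in coefficients, log-likelihood and
  standard errors, with and without ties and strata).

* **Profile in theta.** The EM inner loop is run at fixed `theta`; the
  outer step maximises the gamma-marginal log-likelihood with the Breslow
  plug-in baseline,

  ```
  l(theta) = sum_events [ln lambda0_i + eta_i]
           + sum_j [ lnGamma(a + D_j) - lnGamma(a) + a ln a
                     - (a + D_j) ln(a + H_j) ]
  ```

  with `a = 1/theta`; the `theta -> 0` limit replaces the cluster sum by
  `-sum_j H_j`. The maximiser uses a coarse probe grid followed by bounded
  scalar minimisation (`xatol = 1e-4`); if no probe beats the `theta = 0`
  likelihood the estimate sits on the boundary and the expensive search is
  skipped.

After convergence the posterior frailties are normalised to mean exactly 1
and the baseline is rescaled by the same factor. This is a pure
reparameterisation — `w_j * Lambda0(t)` is unchanged — and restores the
`E[w] = 1` identifiability convention in the reported quantities.

### Testing `theta = 0`

The null hypothesis sits on the boundary of the parameter space, so the
likelihood-ratio statistic is referred to the 50:50 mixture of a point
mass at zero and a chi-square with one degree of freedom: the p-value is
`0.5 * P(chi2_1 > LR)`, and 1 when the estimate is exactly on the
boundary. Monte Carlo calibration under the null (200 replicates in the
acceptance suite) gives a rejection rate of about 0.025 at the 5% level —
the expected mild conservatism of the boundary test at moderate cluster
counts.

### Cluster-robust Cox

`ClusteredCox` delegates to lifelines' `CoxPHFitter` (Efron ties,
`cluster_col` sandwich variance), with fit precision tightened to `1e-9`
so that small-sample closed-form oracles are met to 1e-4 or better. Naive
standard errors are recovered from the observed information at the
estimate; the Breslow baseline at zero covariates is computed per stratum.

## 3. Restricted mean survival time

`RMST(tau)` is the area under the survival curve on `[0, tau]` — the mean
event-free time over a `tau`-day window, which stays interpretable under
heavy censoring where the median may be undefined.

* `rmst_km` integrates the Kaplan-Meier step function exactly (no
  quadrature) and reports the Greenwood-type variance
  `sum_j A_j^2 d_j / (n_j (n_j - d_j))`, where `A_j` is the remaining area
  from event time `j` to `tau`. Without censoring the estimate equals the
  truncated sample mean to 1e-10 and the standard error collapses to
  `sd(min(T, tau)) / sqrt(n)` exactly; under censoring the mean reported
  standard error tracks the Monte Carlo sampling standard deviation within
  a few percent (both verified in the tests).
* `rmst_frailty` integrates the population-averaged adjusted survival
  `mean_j S0(t)^(exp(beta'x) w_j)` over the fitted cluster frailties.
* `rmst_difference` compares two groups with a cluster bootstrap
  (operators resampled with replacement) percentile confidence interval.
* `RMSTFrailtyCox` is the regression analogue: follow-up is
  administratively truncated at `tau` (events after `tau` recoded as
  censored at `tau`) and the frailty model is refit, so coefficients
  describe the hazard within the restricted window.

No extrapolation is allowed: a horizon beyond the observed follow-up
raises `HorizonError`.

## 4. Learning-curve framework

Four classical shape families relate cumulative case volume `n >= 1` to
the probability of success:

```
exponential:   p(n) = a - (a - b) exp(-c (n - 1))
power series:  p(n) = a - (a - b) n^(-c)
logarithmic:   p(n) = b + c ln(n)          (clamped to [0, 1])
log-normal:    p(n) = b + (a - b) Phi((ln n - mu) / sigma)
```

`b` is first-case success, `a` the plateau, `c` the learning rate. Fits
are bounded multi-start nonlinear least squares (`scipy` trust-region
reflective), deterministic given the random state.

The pipeline (`run_lc_pipeline`), for a chosen survival backend (Cox,
frailty Cox, tau-truncated frailty Cox, or random survival forest):

1. **p0** — per-subject predicted survival at the horizon from the backend
   *without* any case-order term: the steady-state success probability.
2. **p1** — the backend is refit with the ordered procedure variable as a
   covariate, a shape is fit to those predictions against case order, and
   `p1_i` is the fitted shape at subject `i`'s order.
3. **p2** — the same family refit to `p1` against the center's cumulative
   case volume (procedures within a center ordered by case order,
   operator id breaking ties, which interleaves concurrent caseloads).
4. **Update** — `tnew_i = (p2_i / p0_i) * T_i`: follow-up is stretched
   where the curve predicts better-than-steady-state success and shrunk
   where it predicts worse. The backend is refit once on the updated times
   (with the order term) to produce the final success probabilities, which
   are binned against volume (width-5 bins) and summarised by a final
   shape fit.
5. **Errors** — `mse1` compares the fitted curve with the *observed*
   marginal success rates (per-bin Kaplan-Meier at the horizon, so the
   comparison stays censoring-consistent); `mse2` compares `p0` with the
   fitted shape values; `mse2_a = MSE(p0, p1)` and `mse2_b = MSE(p1, p2)`
   isolate the two adjustment steps.

Numerical guard rails: `p0` is floored at 1e-6 before the ratio and
updated times at 1e-9, so the refit never sees non-positive durations.

The random survival forest backend delegates the algorithm to
scikit-survival; predictions on the training data are out-of-bag ensemble
averages (falling back, with a warning, to full-ensemble predictions if
the bootstrap bookkeeping is unavailable), which keeps `p0` from being
optimistically overfit.

## 5. Synthetic cohort generator

Event times are exponential given the subject's hazard

```
h_i = baseline_rate * w_op * exp(beta' x_i) * g(n_i)
```

* **Frailties**: operator `w_op ~ Gamma(1/theta, theta)`; an optional
  independent center-level frailty can be switched on (`center_theta`).
* **Covariates**: age, pre-operative Modified Rankin Score, and twelve
  binary covariates drawn to match the marginals of a real
  external-ventricular-drain stroke cohort (age 57.5 ± 14.5, mRS 2.93 ±
  1.67, smoking 48.8%, subarachnoid hemorrhage 52.5%, …). Age and mRS
  enter the linear predictor centered at their means. Default
  log-hazard-ratios mirror the directions of the real adjusted fit
  (smoking ln 2, age 0.03/year, anticoagulant −0.45, …).
* **Learning**: the hazard multiplier is
  `g(n) = -ln p(n) / (baseline_rate * learning_horizon)`, chosen so a
  baseline subject's survival at the learning horizon (30 days) exactly
  traces the target shape `p(n)`. It decreases toward a positive floor as
  experience accumulates.
* **Censoring**: independent exponential (or administrative uniform),
  with the rate calibrated by deterministic bisection on the expected
  censoring fraction `mean(1 - exp(-rate * T_i))` over an independent
  uncensored sample of at least 2000 event times. Realized censoring lands
  within ±3 percentage points of the target at both the 10% and 70%
  conditions.

Seeding uses `numpy.random.SeedSequence` spawning: one stream for the
calibration sample, one for the cohort, so the same seed always yields
byte-identical cohorts.

### Simulation study

Sixteen scenarios cross physicians per center (10 or 5), censoring (10%
or 70%) and the true shape (exponential, power series, logarithmic,
log-normal), in that nesting order, scenario ids 1-16. Defaults: 4
centers, 25 cases per physician, operator frailty variance 0.25, baseline
rate 0.01/day. Replicates default to 50 per backend (10 for the
tau-truncated frailty backend, whose refits are the most expensive);
replicate seeds are `(master * 1000003 + scenario * 1009 + rep) mod 2^31`,
recorded in the study metadata. Failed replicates are counted and
excluded, never imputed.

These problem sizes are package defaults chosen to keep a full study run
tractable on one core; every one of them is a `ScenarioConfig` field or a
`run_study` argument and can be overridden.

## 6. Numerical choices

* Internal Cox solver: Newton-Raphson with step-halving, convergence on
  relative log-likelihood change `1e-9`; Efron tie handling with a fully
  vectorised path when event times are distinct (the generic case for
  continuous simulated times). A singular information matrix raises
  `SingularDesignError`; suspected monotone likelihood (separation) warns
  instead of diverging.
* EM convergence: relative marginal log-likelihood change `1e-8`, warm
  starts across profile evaluations.
* All step-function integrals (KM, RMST, baseline survival) are exact
  sums, not quadrature.
* Every stochastic routine takes an explicit seed and is covered by a
  byte-identical determinism test.

## 7. Limitations

* The frailty standard errors come from the M-step information at the
  final EM iterate and do not propagate the uncertainty in `theta`; the
  Monte Carlo coverage of the 95% intervals in the acceptance suite is
  0.94, so the understatement is mild at these sizes but would matter for
  few, large clusters.
* The gamma-marginal likelihood uses the Breslow plug-in baseline, so
  `theta` comparisons across non-nested models should be treated with
  care.
* The learning-curve update refit is deliberately a single pass, not an
  iteration to a fixed point.
* Under a single linear ordered-procedure covariate, backend predictions
  take an exponential-saturation form in case order regardless of the
  generating shape, so four-way shape comparisons on one cohort are
  weakly identified; cross-scenario comparisons (each scenario fitted
  with its matched shape) are the supported use.
* The random survival forest backend inherits scikit-survival's memory
  appetite; forests above ~500 trees on cohorts above ~10k subjects are
  slow on one core.
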