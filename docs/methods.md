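# Methods

## Problem and models

`zicount` studies a practical modelling question for randomized trials with
zero-inflated count outcomes (serious illness episodes, hospital days, care
days outside the home in a pediatric complex-care telemedicine trial): does a
zero-inflated negative binomial (ZINB) analysis buy anything over a plain
negative binomial (NB) analysis when most counts are zero?

The NB distribution is parameterized by its mean m and a positive shape
(dispersion) r:

    Pr(X = x) = Γ(r + x) / (x! Γ(r)) (r/(r+m))^r (m/(r+m))^x,
    Var(X) = m + m²/r.

The ZINB mixes a point mass p at zero with an NB component:

    Pr(Y = 0) = p + (1 − p)(1 + m/r)^(−r),
    Pr(Y = y) = (1 − p) NB(y; m, r),  y ≥ 1,
    E(Y) = (1 − p) m,   Var(Y) = m(1 − p)(1 + m(p + 1/r)).

Regression attaches a log link with offset to the count mean, log m_i =
x_i'β + offset_i, and a logit link to the structural-zero probability,
logit p_i = z_i'γ. Poisson and ZIP are the r → ∞ limits and are supported as
secondary families.

## Estimation

All four families are fitted by maximum likelihood over (β, γ, log r) with
analytic gradients: L-BFGS-B followed by damped Newton polishing of the
score (target max-norm 1e−6, steps capped at 2 in the sup norm so that a
flat boundary direction is not chased to infinity). A fit is *converged*
when the score max-norm is below 1e−5 and the observed information is finite
and positive definite (Cholesky); three starts (Poisson-initialized, zeros,
perturbed) are tried before declaring failure, with likelihood ties broken by
fewest iterations. The covariance is the inverse observed information
(central differences of the analytic score).

`boundary_flag` marks any zero-part coefficient beyond |20|: the estimated
structural-zero probability has hit 0 or 1 in some arm. When the data carry
no real zero inflation this happens in roughly half the replicates and is
*not* an estimation failure — the fit is the NB limit of the ZINB likelihood
with a perfectly well-defined AIC and count-part estimate — so the default
exclusion rule drops only convergence failures; `drop_boundary=True`
restores the stricter rule as a sensitivity. With the default rule, observed
exclusion rates are ~0% (NB) and ~4–8% (ZINB), the same order as the
original analysis tool reported.

AIC counts every freely estimated parameter, including the dispersion:
q (Poisson), q+1 (NB), q+s (ZIP), q+s+1 (ZINB).

## Profile-likelihood intervals

Confidence intervals invert the likelihood-ratio statistic: endpoints solve
2(ℓ_max − ℓ_profile(ψ)) = χ²₁(level), profiling over *all* nuisance
parameters including log r (the source study does not say whether its
intervals profiled the dispersion; profiling everything is the standard
definition and is what we do). The bracket grows geometrically from the Wald
interval; the root is found by bracketed bisection (Brent) to 1e−6 on the
coefficient scale with warm-started nuisance optimizations. A monotone
profile yields an infinite endpoint flagged `unbounded`; any machinery
failure falls back to a Wald interval labelled `wald_fallback`.

## Synthetic-trial generator

Each replicate emulates the n = 422 two-arm trial. Predictor-distribution
hyperparameters are redrawn per replicate from uniform ranges: treatment
probability U(0.45, 0.55); three baseline-risk weights U(0.20, 0.45)
renormalized; age ~ truncated normal on (0, 18) years with mean U(3, 7) and
SD 4, dichotomized at 2 years. The exact ranges used in the original study
are not published; these are plausible for a pediatric complex-care trial
and are config-overridable. Follow-up is a constant log-offset of 0
(absorbed into the calibrated intercept); a per-subject offset can be
supplied through the data interface.

The generative truth uses the published data-derived (DD) regression slopes
for treatment, age stratum, and the two risk dummies (e.g., primary outcome:
NB truth treatment −0.49; ZINB truth treatment −0.64 with a zero-part
treatment coefficient of −15.66). The count intercept β₀ and dispersion r
are not published; they are **calibrated** so that the across-replicate
median overall mean and median zero percentage hit the published
synthetic-outcome medians (0.68 and 69.9% for the primary outcome). The
calibration root-finds on the analytic per-replicate expected mean and
expected zero mass over a fixed batch of 200 predictor replicates — the mean
identifies β₀ alone through the log link (monotone), then the zero target
identifies r (monotone given the mean) — which is deterministic, smooth, and
indistinguishable from matching empirical medians at these sample sizes.
The ZINB zero-part intercept is held fixed during calibration (two targets
identify two parameters): −2.944 (≈5% structural zeros in the control arm,
≈0 under treatment) for the two zero-inflated outcomes, consistent with the
near-identity of the published NB- and ZINB-generated outcome summaries, and
−5.293 (≈0.5%) for care days outside the home, whose ~5% total zeros sit
below the structural floor the shared default would impose. Both are
overridable.

Counts are drawn as a gamma–Poisson mixture; ZINB replaces a draw with a
structural zero with probability p_i. Randomness is keyed by (master seed,
replicate index) through `SeedSequence`, so any execution order — serial or
parallel — reproduces identical datasets and each replicate can be
regenerated in isolation.

What the generator does *not* emulate: the real trial's covariate joint
distribution, follow-up censoring, and any residual dependence between
predictors and the zero process beyond treatment. Passing tests therefore
demonstrate correct behaviour under the stated generative families, not
performance guarantees on arbitrary real data.

## Simulation metrics

Following the source study's table arithmetic, *absolute bias* is the mean
absolute error E|β̂ − β_DD| (the printed relative-bias values equal absolute
bias divided by |β_DD| only under this reading, and a genuine 0.18 systematic
bias for a correctly specified MLE at n = 422 would be implausible); the
signed mean bias is computed alongside. MSE is the mean squared error;
coverage is the fraction of profile intervals containing β_DD. Exclusion is
per analysis family, so a failed ZINB fit does not discard the NB estimate.
AIC ties count as NB-preferred (parsimony; a probability-zero event stated
for determinism).

## Preference meta-regression

Each kept replicate contributes a binary outcome (1 = ZINB had the lower
AIC) and 8 characteristics of its outcome vector: overall mean and variance,
zero percentage (0–100 scale), mean/variance/skewness of the non-zero part
(adjusted Fisher–Pearson skewness, the common software default; the
unadjusted variant is a switch), and the marginal NB MLEs of p = r/(r+m)
and r (mean fixed at the sample mean by the score equation, shape by
one-dimensional profile maximization; underdispersed samples cap r at 1e6
with a Poisson-limit flag, and samples whose NB likelihood gain over the
Poisson is below the 95% χ²₁ critical value are flagged as effectively
Poisson). Replicates with undefined skewness (fewer than 3 non-zero counts)
are dropped with a count.

Predictors are standardized to mean 0, SD 1. The multivariable fit is
L2-penalized logistic regression (intercept unpenalized), penalty weight λ
chosen from a 50-point logarithmic grid (1e−3 to 1e3) by 10-fold stratified
cross-validated binomial deviance at a fixed fold seed, using the
one-standard-error rule: the deviance curve is nearly flat in λ for these 8
highly correlated predictors, and the bare minimum sits close to zero
penalty, where collinear coefficient pairs (overall mean and zero
percentage) inflate each other and the adjusted ORs lose meaning. The
heaviest penalty within one SE of the minimum — the standard remedy, and
`cv.glmnet`'s — lands in the regime where the OR scale matches published
ridge analyses of this kind; `one_se_rule=False` restores bare-minimum
selection. Because the original penalty-selection rule is unpublished, exact
odds-ratio magnitudes carry no reproduction guarantee; the rank ordering of
the adjusted ORs is the claim that is tested. Univariable logistic fits are reported on both the standardized and
raw scales (the raw OR equals the standardized OR^(1/sd)); separation yields
an infinite-OR sentinel. Ridge ORs get nonparametric bootstrap percentile
intervals (200 resamples, penalty fixed), since penalized-fit standard
errors are not well defined.

## Problem sizes and numerical choices

The packaged study defaults run 500 replicates per scenario at n = 422 (the
full published design used 5000; the `reps` switch scales up). Calibration
uses 200 predictor batches. The sensitivity grid for n is {60, 80, 100,
200, 422, 600, 800}; sizes below 60 are rejected because ~70% zeros would
leave under ~15 non-zero counts. Optimizer tolerances: L-BFGS-B ftol 1e−13,
gtol 1e−6; profile nuisance optimizations ftol 1e−14/gtol 1e−10 with a short
Newton polish; χ² endpoint condition reproduced to ~1e−4. Degenerate inputs
(all-zero outcome, singular design, n < q+s+2) raise immediately with the
offending condition named; overflow of the simulation linear predictor
reports the offending value.

## Known limitations

* Hurdle, ZI Conway–Maxwell–Poisson, and ZI generalized Poisson families are
  out of scope, as are Vuong tests and Bayesian estimation.
* Coverage of profile intervals at these settings runs ~1–2 points below
  nominal (0.93–0.95 observed at 500 replicates); this is consistent with
  asymptotic intervals at n = 422 with ~70% zeros.
* The ridge OR magnitudes depend on the penalty-selection rule; only the
  ranking is stable.
* Calibrated (β₀, r) depend on the assumed predictor-hyperparameter ranges;
  both are reported in the run log and overridable.
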