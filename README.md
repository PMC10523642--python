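# zicount

Count outcomes in clinical trials — serious illness episodes, days in
hospital, emergency visits — are typically non-negative, right-skewed,
overdispersed, and dominated by zeros. Zero-inflated regression models such
as the zero-inflated negative binomial (ZINB) exist for exactly this shape
of data, but whether they actually beat a plain negative binomial (NB)
analysis for the quantity trials care about (the treatment effect) is an
empirical question. `zicount` is a simulation laboratory for that question,
built around a pediatric complex-care telemedicine trial (n = 422, ~70%
zeros in the primary outcome): it fits NB/ZINB (and Poisson/ZIP) count
regressions by maximum likelihood with profile-likelihood intervals,
generates calibrated synthetic trial replicates from the trial's published
data-derived coefficients, compares analyses by bias, MSE, coverage, and
AIC, and asks — via ridge logistic meta-regression — which characteristics
of an outcome actually predict a ZINB preference.

## Models

The NB has mean m and dispersion (shape) r, with Var = m + m²/r; the ZINB
mixes a structural-zero mass p with an NB component:

    Pr(Y=0) = p + (1−p)(1 + m/r)^(−r),   Pr(Y=y) = (1−p)·NB(y; m, r) for y ≥ 1,
    E(Y) = (1−p)m,   Var(Y) = m(1−p)(1 + m(p + 1/r)).

Regression: log m_i = x_i'β + offset_i (log follow-up) and logit p_i = z_i'γ.
Fitting is quasi-Newton with analytic gradients and Newton polishing;
confidence intervals invert the likelihood-ratio statistic
2(ℓ_max − ℓ_profile(ψ)) = χ²₁ over all nuisance parameters. See
`docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from zicount import CountModel, StudyConfig
from zicount.study import calibrate_generative_model
from zicount.synthetic import simulate_dataset

cfg = StudyConfig(master_seed=2023)
model = calibrate_generative_model(cfg, "nb")   # primary outcome, NB truth
ds = simulate_dataset(model, 422, master_seed=2023, replicate_id=0)
res = CountModel.from_data(ds.data, family="nb").fit()
print(res.summary())
ci = res.profile_ci(1)                           # treatment coefficient
print(f"profile CI for treatment: ({ci.lower:.4f}, {ci.upper:.4f})")
```

prints

```
NB count regression (n=422)
log-likelihood -401.2257   AIC 814.4515   params 6   converged True
term                    coef     std err
const                 0.7643      0.3264
treatment            -0.4742      0.2050
age_ge2              -0.7129      0.3025
risk2                -0.2558      0.2351
risk3                -1.5196      0.2542
log_r                -0.7088      0.1865
dispersion r = 0.4922
profile CI for treatment: (-0.8808, -0.0722)
```

The calibrated truth for this scenario has treatment coefficient −0.49 (the
data-derived value), intercept 1.046 and dispersion 0.479 (solved so the
median synthetic outcome has mean 0.68 with 69.9% zeros); this replicate
recovers the treatment effect at −0.474 with a profile interval covering the
truth. Fitting the same dataset with `family="zinb"` gives a higher AIC
(815.8 vs 814.5) — the two extra zero-inflation parameters don't pay for
themselves, the pattern that holds in >80% of replicates.

## Command line

```
zicount calibrate --outcome serious_illness --dd-model nb --seed 2023
zicount simulate  --n 422 --seed 2023 --out ds.csv
zicount analyze   --data ds.csv --families nb,zinb
zicount run-all   --reps 500 --seed 2023 --out results/
```

`run-all` writes `replicates.csv`, `summary.csv` (bias/MSE/coverage per
generative × analysis family), `preference.csv` (% of replicates preferring
NB by AIC), `odds_ratios.csv` (ridge-adjusted and univariable ORs for the 8
outcome characteristics), `exclusions.csv`, and a run log. A given
(config, seed) reproduces all outputs byte-identically.

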