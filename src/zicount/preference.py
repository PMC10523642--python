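"""Which outcome characteristics predict a ZINB preference? Ridge logistic fit.

Each kept replicate contributes a binary outcome (1 when the ZINB fit had the
lower AIC) and the 8 outcome characteristics as predictors.  Because those
characteristics are highly correlated, the multivariable fit uses an L2
(ridge) penalty on the standardized coefficients, with the penalty weight
chosen by K-fold cross-validated binomial deviance.  Univariable logistic
fits on both the standardized and raw predictor scales are reported
alongside; bootstrap percentile intervals quantify the ridge ORs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .characteristics import CHARACTERISTIC_NAMES

__all__ = [
    "PreferenceDataset",
    "RidgeFitResult",
    "PreferenceModel",
    "build_preference_dataset",
    "fit_ridge_logistic",
    "unadjusted_ors",
    "default_lambda_grid",
]

#: separation sentinel for univariable odds ratios
OR_INF = np.inf


def default_lambda_grid(num: int = 50) -> np.ndarray:
    """50-point logarithmic grid for the L2 penalty weight."""
    return np.logspace(-3.0, 3.0, num)


@dataclass
class PreferenceDataset:
    """Binary ZINB-preference outcome plus standardized characteristic predictors."""

    outcome: np.ndarray  # 1 = ZINB preferred by AIC
    predictors_raw: pd.DataFrame  # 8 columns, original scale
    predictors_std: np.ndarray
    scaling: pd.DataFrame  # per-predictor mean and sd
    n_dropped_undefined: int = 0

    @property
    def names(self):
        return list(self.predictors_raw.columns)


def build_preference_dataset(records) -> PreferenceDataset:
    """Code the AIC-preference outcome and standardize the 8 predictors.

    ``records`` should already have passed exclusion for both analysis
    families.  Replicates whose non-zero skewness is undefined (fewer than 3
    non-zero counts) are dropped and counted.  Ties in AIC code as 0 (NB
    preferred).
    """
    rows, ys = [], []
    n_dropped = 0
    for rec in records:
        nb, zinb = rec.fits.get("nb"), rec.fits.get("zinb")
        if nb is None or zinb is None or rec.characteristics is None:
            continue
        if not (np.isfinite(nb.aic) and np.isfinite(zinb.aic)):
            continue
        vec = rec.characteristics.predictor_vector()
        if not np.all(np.isfinite(vec)):
            n_dropped += 1
            continue
        rows.append(vec)
        ys.append(1 if zinb.aic < nb.aic else 0)
    if len(rows) < 2:
        raise ValueError("too few usable replicates to build a preference dataset")
    if len(rows) < 50:
        warnings.warn(
            f"only {len(rows)} usable replicates; preference regression will be noisy",
            stacklevel=2,
        )
    raw = pd.DataFrame(np.asarray(rows), columns=CHARACTERISTIC_NAMES)
    mean = raw.mean()
    sd = raw.std(ddof=1)
    tol = 1e-10 * np.maximum(1.0, mean.abs())
    constant = sd[sd <= tol].index.tolist()
    if constant:
        raise ValueError(f"constant predictor column(s): {constant}; ridge needs finite scaling")
    std = ((raw - mean) / sd).to_numpy()
    return PreferenceDataset(
        outcome=np.asarray(ys, dtype=int),
        predictors_raw=raw,
        predictors_std=std,
        scaling=pd.DataFrame({"mean": mean, "sd": sd}),
        n_dropped_undefined=n_dropped,
    )


def _fit_at_lambda(X, y, lam):
    # sklearn's objective is sum(logloss) + (1/(2C)) ||w||^2, so C = 1/lambda;
    # lambda = 0 (C = inf) is the unpenalized fit
    C = np.inf if lam <= 0 else 1.0 / lam
    est = LogisticRegression(
        C=C, solver="lbfgs", max_iter=20000, tol=1e-12, fit_intercept=True
    )
    est.fit(X, y)
    return est


@dataclass
class RidgeFitResult:
    """Selected-penalty ridge logistic fit with odds ratios on several scales."""

    lambda_: float
    intercept: float
    coefficients: np.ndarray  # standardized scale
    adjusted_or: pd.Series  # exp(coefficients)
    cv_deviance_path: pd.DataFrame
    unadjusted_or_std: pd.Series = None
    unadjusted_or_raw: pd.Series = None
    bootstrap_ci: pd.DataFrame = None
    names: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"adjusted_or": self.adjusted_or})
        if self.unadjusted_or_std is not None:
            out["unadjusted_or_std"] = self.unadjusted_or_std
        if self.unadjusted_or_raw is not None:
            out["unadjusted_or_raw"] = self.unadjusted_or_raw
        if self.bootstrap_ci is not None:
            out = out.join(self.bootstrap_ci)
        return out


def fit_ridge_logistic(
    dataset: PreferenceDataset,
    lambda_grid=None,
    cv_folds: int = 10,
    rng=None,
    n_bootstrap: int = 0,
    one_se_rule: bool = True,
) -> RidgeFitResult:
    """L2-penalized logistic regression with CV-selected penalty.

    The penalty applies to the standardized characteristic coefficients only
    (the intercept is unpenalized); ``lambda`` multiplies ``0.5 * ||w||^2``
    against the summed binomial log-loss.  By default the heaviest penalty
    whose mean CV deviance is within one standard error of the minimum is
    selected: with 8 highly correlated predictors the deviance curve is
    nearly flat in the penalty, and the bare minimum sits close to zero
    penalty where collinear coefficient pairs inflate each other.
    ``one_se_rule=False`` selects the minimum-deviance penalty instead.
    Optional nonparametric bootstrap (resampling replicates, penalty held
    fixed) gives percentile intervals for the adjusted ORs.
    """
    y = dataset.outcome
    X = dataset.predictors_std
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite predictors")
    if len(np.unique(y)) < 2:
        raise ValueError("preference outcome has a single class; nothing to fit")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if rng is None:
        rng = np.random.default_rng(0)
    fold_seed = int(rng.integers(2**31 - 1))
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=fold_seed)

    eps = 1e-12
    mean_dev, se_dev = [], []
    for lam in lambda_grid:
        devs = []
        for train, test in cv.split(X, y):
            est = _fit_at_lambda(X[train], y[train], lam)
            p = np.clip(est.predict_proba(X[test])[:, 1], eps, 1 - eps)
            devs.append(-2.0 * np.mean(y[test] * np.log(p) + (1 - y[test]) * np.log1p(-p)))
        mean_dev.append(np.mean(devs))
        se_dev.append(np.std(devs, ddof=1) / np.sqrt(len(devs)))
    mean_dev = np.asarray(mean_dev)
    se_dev = np.asarray(se_dev)
    best = int(np.argmin(mean_dev))
    if one_se_rule:
        threshold = mean_dev[best] + se_dev[best]
        within = np.flatnonzero(mean_dev <= threshold)
        best = int(within[np.argmax(lambda_grid[within])])
    lam = float(lambda_grid[best])

    est = _fit_at_lambda(X, y, lam)
    coefs = est.coef_.ravel()
    names = dataset.names
    result = RidgeFitResult(
        lambda_=lam,
        intercept=float(est.intercept_[0]),
        coefficients=coefs,
        adjusted_or=pd.Series(np.exp(coefs), index=names),
        cv_deviance_path=pd.DataFrame(
            {"lambda": lambda_grid, "mean_cv_deviance": mean_dev, "se_cv_deviance": se_dev}
        ),
        names=names,
    )

    una = unadjusted_ors(dataset)
    result.unadjusted_or_std = una["or_std"]
    result.unadjusted_or_raw = una["or_raw"]

    if n_bootstrap > 0:
        n = len(y)
        boot = np.empty((n_bootstrap, len(names)))
        for b in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if len(np.unique(yb)) < 2:
                boot[b] = np.nan
                continue
            eb = _fit_at_lambda(X[idx], yb, lam)
            boot[b] = np.exp(eb.coef_.ravel())
        lo = np.nanpercentile(boot, 2.5, axis=0)
        hi = np.nanpercentile(boot, 97.5, axis=0)
        result.bootstrap_ci = pd.DataFrame(
            {"or_ci_lower": lo, "or_ci_upper": hi}, index=names
        )
    return result


def unadjusted_ors(dataset: PreferenceDataset) -> pd.DataFrame:
    """One single-predictor logistic fit per characteristic.

    Returns odds ratios on the standardized scale and on the raw scale (the
    actual per-unit increment).  Separation or non-convergence yields an
    infinite-OR sentinel and a flag rather than an exception.
    """
    y = dataset.outcome
    rows = {}
    for j, name in enumerate(dataset.names):
        row = {}
        for scale, x in (
            ("std", dataset.predictors_std[:, j]),
            ("raw", dataset.predictors_raw[name].to_numpy(float)),
        ):
            design = sm.add_constant(x)
            flagged = False
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.Logit(y, design).fit(disp=0, maxiter=500)
                coef = res.params[1]
                if not res.mle_retvals.get("converged", True) or abs(coef) > 30:
                    flagged = True
            except Exception:
                coef, flagged = np.nan, True
            if flagged:
                or_val = OR_INF if (np.isnan(coef) or coef > 0) else 0.0
            else:
                or_val = float(np.exp(coef))
            row[f"or_{scale}"] = or_val
            row[f"separation_{scale}"] = flagged
        rows[name] = row
    return pd.DataFrame(rows).T.astype(
        {"or_std": float, "or_raw": float, "separation_std": bool, "separation_raw": bool}
    )


class PreferenceModel:
    """Model-object wrapper: ``PreferenceModel(records).fit()`` -> RidgeFitResult."""

    def __init__(self, records=None, dataset: PreferenceDataset = None):
        if dataset is None:
            if records is None:
                raise ValueError("provide records or a prebuilt dataset")
            dataset = build_preference_dataset(records)
        self.dataset = dataset

    def fit(self, **kwargs) -> RidgeFitResult:
        return fit_ridge_logistic(self.dataset, **kwargs)
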