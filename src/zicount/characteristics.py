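"""Summary characteristics of a count outcome used as meta-regression predictors.

Eight statistics summarize each simulated outcome vector: overall mean and
variance, percentage of zeros, mean/variance/skewness of the non-zero part,
and the marginal negative-binomial maximum-likelihood estimates of the
success probability ``p = r / (r + m)`` and the shape ``r``.  An outcome is
flagged *zero-inflated* when more than 60% of counts are zero and the sample
variance exceeds the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize
from scipy.special import gammaln
from scipy.stats import skew

__all__ = [
    "OutcomeCharacteristics",
    "compute_characteristics",
    "marginal_nb_mle",
    "CHARACTERISTIC_NAMES",
]

CHARACTERISTIC_NAMES = [
    "overall_mean",
    "overall_variance",
    "pct_zero",
    "nonzero_mean",
    "nonzero_variance",
    "nonzero_skewness",
    "mle_p",
    "mle_r",
]

#: cap on the marginal NB shape; reaching it means the sample is effectively Poisson
R_CAP = 1e6


@dataclass
class OutcomeCharacteristics:
    overall_mean: float
    overall_variance: float
    pct_zero: float  # 0-100 scale
    nonzero_mean: float
    nonzero_variance: float
    nonzero_skewness: float  # NaN when fewer than 3 non-zero values
    mle_p: float
    mle_r: float
    is_zero_inflated: bool
    skewness_defined: bool = True
    poisson_limit: bool = False

    def as_dict(self) -> dict:
        return asdict(self)

    def predictor_vector(self) -> np.ndarray:
        d = self.as_dict()
        return np.array([d[k] for k in CHARACTERISTIC_NAMES], dtype=float)


def marginal_nb_mle(counts) -> tuple[float, float, bool]:
    """Covariate-free NB maximum likelihood: returns ``(mle_p, mle_r, poisson_limit)``.

    The score equation fixes the fitted mean at the sample mean; the shape is
    found by one-dimensional profile maximization on the log scale.  For
    underdispersed samples (variance <= mean) the shape diverges; it is capped
    at 1e6 and the Poisson-limit flag raised.
    """
    y = np.asarray(counts, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts must be non-negative integers")
    m_hat = y.mean()
    if m_hat <= 0:
        raise ValueError("all-zero sample: the marginal NB mean is degenerate")
    var = y.var(ddof=1)

    def negll_logr(log_r):
        r = np.exp(log_r)
        return -np.sum(
            gammaln(r + y)
            - gammaln(y + 1.0)
            - gammaln(r)
            + r * (np.log(r) - np.log(r + m_hat))
            + y * (np.log(m_hat) - np.log(r + m_hat))
        )

    if var <= m_hat:
        r_hat, flag = R_CAP, True
    else:
        res = optimize.minimize_scalar(
            negll_logr, bounds=(np.log(1e-8), np.log(R_CAP)), method="bounded",
            options={"xatol": 1e-10},
        )
        r_hat = float(np.exp(res.x))
        if r_hat >= R_CAP * 0.99:
            r_hat = R_CAP
        # near-Poisson flag: the NB's likelihood gain over the Poisson at the
        # same mean is below the 95% chi-square(1) critical value
        ll_pois = float(np.sum(-m_hat + y * np.log(m_hat) - gammaln(y + 1.0)))
        flag = 2.0 * (-negll_logr(np.log(r_hat)) - ll_pois) < 3.841458820694124
    p_hat = r_hat / (r_hat + m_hat)
    return float(p_hat), float(r_hat), bool(flag)


def compute_characteristics(counts, adjusted_skewness: bool = True) -> OutcomeCharacteristics:
    """Compute the 8 summary characteristics of a count vector.

    ``adjusted_skewness`` selects the adjusted Fisher-Pearson standardized
    third moment (the default of mainstream statistics software); switch off
    for the unadjusted estimator.  Sample variances use the n-1 denominator.
    The decomposition ``overall_mean = (1 - pct_zero/100) * nonzero_mean``
    holds exactly for every input.
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("need a 1-d vector of at least 3 counts")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts must be non-negative integers")
    if not np.any(y > 0):
        raise ValueError("all-zero outcome vector: characteristics are degenerate")

    nz = y[y > 0]
    pct_zero = 100.0 * (1.0 - nz.size / y.size)
    nonzero_mean = float(nz.mean())
    nonzero_var = float(nz.var(ddof=1)) if nz.size >= 2 else 0.0
    skew_defined = nz.size >= 3 and nz.var() > 0
    if skew_defined:
        nz_skew = float(skew(nz, bias=not adjusted_skewness))
    else:
        nz_skew = np.nan

    overall_mean = float(y.mean())
    overall_var = float(y.var(ddof=1))
    mle_p, mle_r, poisson_limit = marginal_nb_mle(y.astype(int))

    return OutcomeCharacteristics(
        overall_mean=overall_mean,
        overall_variance=overall_var,
        pct_zero=float(pct_zero),
        nonzero_mean=nonzero_mean,
        nonzero_variance=nonzero_var,
        nonzero_skewness=nz_skew,
        mle_p=mle_p,
        mle_r=mle_r,
        is_zero_inflated=bool(pct_zero > 60.0 and overall_var > overall_mean),
        skewness_defined=bool(skew_defined),
        poisson_limit=poisson_limit,
    )
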