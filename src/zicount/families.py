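"""Log probability mass functions and moments for zero-inflated count families.

The negative binomial (NB) is parameterized by its mean ``m`` and a positive
dispersion (shape) parameter ``r``::

    Pr(X = x) = Gamma(r + x) / (x! Gamma(r)) * (r / (r + m))**r * (m / (r + m))**x

with ``Var(X) = m + m**2 / r``; ``r -> inf`` recovers the Poisson.  The
zero-inflated NB (ZINB) mixes a point mass ``p`` at zero with an NB(m, r)
component, so ``E(Y) = (1 - p) m`` and
``Var(Y) = m (1 - p) (1 + m (p + 1/r))``.

Everything is computed in log space (log-gamma, log-sum-exp); raw factorials
are never formed.  All functions accept scalars or numpy arrays.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "nb_log_pmf",
    "zinb_log_pmf",
    "poisson_log_pmf",
    "zip_log_pmf",
    "zinb_moments",
    "nb_zero_prob",
]


def _check_counts(x, name: str = "x") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError(f"{name} must contain finite non-negative integers")
    return x


def _check_positive(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise ValueError(f"{name} must be finite and > 0")
    return v


def nb_log_pmf(x, m, r):
    """Log PMF of the negative binomial with mean ``m`` and dispersion ``r``.

    Parameters
    ----------
    x : int or array_like
        Non-negative integer counts.
    m : float or array_like
        Mean, > 0.
    r : float or array_like
        Dispersion (shape), > 0.  Small ``r`` means heavy overdispersion.
    """
    x = _check_counts(x)
    m = _check_positive(m, "m")
    r = _check_positive(r, "r")
    out = (
        gammaln(r + x)
        - gammaln(x + 1.0)
        - gammaln(r)
        + r * (np.log(r) - np.log(r + m))
        + x * (np.log(m) - np.log(r + m))
    )
    return out if out.ndim else float(out)


def poisson_log_pmf(x, m):
    """Log PMF of the Poisson with mean ``m``."""
    x = _check_counts(x)
    m = _check_positive(m, "m")
    out = -m + x * np.log(m) - gammaln(x + 1.0)
    return out if out.ndim else float(out)


def _zi_log_pmf(y, p_zero, log_base_pmf_y, log_base_pmf_zero):
    """Mix a point mass at zero into a base count log-PMF (log-sum-exp on y=0)."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p_zero, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p_zero must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        log_p = np.log(p)
        log_1mp = np.log1p(-p)
    zero_branch = logsumexp(
        np.stack(np.broadcast_arrays(log_p, log_1mp + log_base_pmf_zero)), axis=0
    )
    pos_branch = log_1mp + log_base_pmf_y
    out = np.where(y == 0, zero_branch, pos_branch)
    return out if out.ndim else float(out)


def zinb_log_pmf(y, p_zero, m, r):
    """Log PMF of the zero-inflated negative binomial.

    ``y = 0`` has mass ``p + (1 - p) (1 + m/r)**(-r)``; ``y >= 1`` has mass
    ``(1 - p)`` times the NB(m, r) mass.  ``p_zero = 0`` reduces exactly to
    :func:`nb_log_pmf`; ``p_zero = 1`` puts all mass at zero.
    """
    y = _check_counts(y, "y")
    base = nb_log_pmf(y, m, r)
    m_ = _check_positive(m, "m")
    r_ = _check_positive(r, "r")
    base_zero = r_ * (np.log(r_) - np.log(r_ + m_))
    return _zi_log_pmf(y, p_zero, base, base_zero)


def zip_log_pmf(y, p_zero, m):
    """Log PMF of the zero-inflated Poisson."""
    y = _check_counts(y, "y")
    base = poisson_log_pmf(y, m)
    return _zi_log_pmf(y, p_zero, base, -np.asarray(m, dtype=float))


def zinb_moments(p_zero, m, r):
    """Mean and variance of the ZINB distribution.

    Returns ``((1 - p) m, m (1 - p) (1 + m (p + 1/r)))``.  With ``p_zero = 0``
    this is the NB pair ``(m, m + m**2/r)``; with ``p_zero = 1`` it degenerates
    to ``(0, 0)``.
    """
    p = np.asarray(p_zero, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p_zero must lie in [0, 1]")
    m = _check_positive(m, "m")
    r = _check_positive(r, "r")
    mean = (1.0 - p) * m
    var = m * (1.0 - p) * (1.0 + m * (p + 1.0 / r))
    if np.ndim(mean) == 0:
        return float(mean), float(var)
    return mean, var


def nb_zero_prob(m, r):
    """Probability of a zero count under NB(m, r): ``(r / (r + m))**r``."""
    m = _check_positive(m, "m")
    r = _check_positive(r, "r")
    out = np.exp(r * (np.log(r) - np.log(r + m)))
    return out if np.ndim(out) else float(out)
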