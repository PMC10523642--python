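"""Maximum-likelihood count regression (Poisson, NB, ZIP, ZINB).

The count mean uses a log link plus an offset, ``log m_i = x_i' beta +
offset_i``; zero-inflated families add a logit-linked structural-zero
probability, ``logit p_i = z_i' gamma``.  The NB dispersion ``r`` is
optimized on the log scale so positivity is automatic.

Fitting is quasi-Newton (L-BFGS-B) with analytic gradients, followed by a few
Newton polishing steps on the full parameter vector so the score is driven to
machine-level zero; three starts (Poisson-initialized, zeros, perturbed) are
tried before a fit is declared non-converged.  Results objects carry the
covariance (inverse observed information), AIC, convergence/boundary flags,
profile-likelihood confidence intervals, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import digamma, expit, gammaln
from scipy.stats import chi2, norm

from .data import RegressionData

__all__ = ["CountModel", "CountResults", "ProfileInterval", "model_aic", "profile_ci"]

FAMILIES = ("poisson", "nb", "zip", "zinb")
_ZI_FAMILIES = ("zip", "zinb")
_DISPERSED = ("nb", "zinb")

#: |logit coefficient| beyond this is treated as a boundary (p -> 0 or 1) fit
BOUNDARY_LOGIT = 20.0
#: max-norm of the score below which a fit counts as converged
GRAD_TOL = 1e-5


@dataclass
class ProfileInterval:
    """A likelihood-based (or fallback Wald) confidence interval."""

    lower: float
    upper: float
    level: float
    method: str = "profile"  # "profile" or "wald_fallback"
    unbounded: bool = False

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def _softplus(u):
    return np.logaddexp(0.0, u)


class CountModel:
    """Count regression model for one of the four supported families.

    Parameters
    ----------
    endog : array_like
        Non-negative integer counts.
    exog : array_like, shape (n, q)
        Count-part design matrix including an intercept column.
    exog_infl : array_like, shape (n, s), optional
        Zero-part design matrix (required for "zip"/"zinb").
    offset : array_like, optional
        Log-exposure added to the count linear predictor.
    family : {"poisson", "nb", "zip", "zinb"}
    """

    def __init__(self, endog, exog, exog_infl=None, offset=None, family="nb"):
        if family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        self.family = family
        self.is_zi = family in _ZI_FAMILIES
        self.has_dispersion = family in _DISPERSED
        if self.is_zi and (exog_infl is None or np.size(exog_infl) == 0):
            raise ValueError(f"family '{family}' requires exog_infl")
        data = RegressionData(
            outcome=endog,
            count_covariates=exog,
            logit_covariates=exog_infl if self.is_zi else None,
        )
        self.y = data.outcome.astype(float)
        self.X = data.count_covariates
        self.Z = data.logit_covariates if self.is_zi else np.empty((data.n, 0))
        self.offset = (
            np.zeros(data.n) if offset is None else np.asarray(offset, dtype=float)
        )
        self.k_count = self.X.shape[1]
        self.k_infl = self.Z.shape[1]
        self.k_params = self.k_count + self.k_infl + int(self.has_dispersion)
        self.nobs = data.n
        if self.nobs < self.k_params + 1:
            raise ValueError("too few observations for the number of parameters")
        if np.linalg.matrix_rank(self.X) < self.k_count:
            raise ValueError("singular count design matrix")
        if self.k_infl and np.linalg.matrix_rank(self.Z) < self.k_infl:
            raise ValueError("singular zero-part design matrix")
        if family in ("poisson", "nb") and not np.any(self.y > 0):
            raise ValueError(
                f"outcome is identically zero: the {family} mean model is degenerate"
            )
        self.param_names = self._make_names(exog, exog_infl)
        self._zero_mask = self.y == 0
        self._pos_mask = ~self._zero_mask

    @classmethod
    def from_data(cls, data: RegressionData, family="nb"):
        """Build from a :class:`~zicount.data.RegressionData` container."""
        m = cls(
            endog=data.outcome,
            exog=data.count_covariates,
            exog_infl=data.logit_covariates if family in _ZI_FAMILIES else None,
            offset=data.offset_log,
            family=family,
        )
        m.param_names = list(data.count_names)
        if m.is_zi:
            m.param_names += list(data.logit_names)
        if m.has_dispersion:
            m.param_names += ["log_r"]
        return m

    @classmethod
    def from_dataframe(cls, df, family="nb"):
        """Build from a table with the standard trial columns (see data module)."""
        return cls.from_data(RegressionData.from_dataframe(df), family=family)

    def _make_names(self, exog, exog_infl):
        names = [f"x{j}" for j in range(self.k_count)]
        if hasattr(exog, "columns"):
            names = list(exog.columns)
        infl = [f"infl_z{j}" for j in range(self.k_infl)]
        if exog_infl is not None and hasattr(exog_infl, "columns"):
            infl = [f"infl_{c}" for c in exog_infl.columns]
        return names + infl + (["log_r"] if self.has_dispersion else [])

    # ------------------------------------------------------------------ #
    # likelihood                                                          #
    # ------------------------------------------------------------------ #

    def _split(self, params):
        q, s = self.k_count, self.k_infl
        beta = params[:q]
        gamma = params[q : q + s]
        log_r = params[q + s] if self.has_dispersion else None
        return beta, gamma, log_r

    def loglike(self, params):
        """Total log-likelihood at ``params``."""
        return -self._nll_grad(np.asarray(params, dtype=float))[0]

    def score(self, params):
        """Gradient of the log-likelihood."""
        return -self._nll_grad(np.asarray(params, dtype=float))[1]

    def _nll_grad(self, params):
        beta, gamma, log_r = self._split(params)
        eta = self.X @ beta + self.offset
        eta = np.clip(eta, -700, 700)
        m = np.exp(eta)
        y = self.y
        grad = np.zeros_like(params)
        q, s = self.k_count, self.k_infl

        if self.has_dispersion:
            r = np.exp(np.clip(log_r, -300, 300))
            log_q0 = r * (log_r - np.log(r + m))  # log P(0) under NB(m, r)
            ll_count = (
                gammaln(r + y)
                - gammaln(y + 1.0)
                - gammaln(r)
                + r * (log_r - np.log(r + m))
                + y * (eta - np.log(r + m))
            )
            dl_deta_count = y - (r + y) * m / (r + m)
            dl_dlogr_count = r * (
                digamma(r + y) - digamma(r) + log_r - np.log(r + m) + (m - y) / (r + m)
            )
        else:
            log_q0 = -m
            ll_count = -m + y * eta - gammaln(y + 1.0)
            dl_deta_count = y - m
            dl_dlogr_count = None

        if not self.is_zi:
            nll = -float(np.sum(ll_count))
            grad[:q] = -(self.X.T @ dl_deta_count)
            if self.has_dispersion:
                grad[q] = -float(np.sum(dl_dlogr_count))
            return nll, grad

        u = np.clip(self.Z @ gamma, -700, 700)
        p = expit(u)
        log_p = -_softplus(-u)
        log_1mp = -_softplus(u)
        zero = self._zero_mask
        # y = 0: log(p + (1-p) q0); y > 0: log(1-p) + count term
        ll0 = np.logaddexp(log_p[zero], log_1mp[zero] + log_q0[zero])
        ll = np.where(zero, 0.0, log_1mp + ll_count)
        nll = -float(np.sum(ll[~zero]) + np.sum(ll0))

        # structural-zero posterior weight on the NB component, zero obs only
        w_nb = np.exp(log_1mp[zero] + log_q0[zero] - ll0)
        dl_deta = np.where(zero, 0.0, dl_deta_count)
        if self.has_dispersion:
            rz = r if np.ndim(r) == 0 else r
            dl_deta_zero = -w_nb * rz * m[zero] / (rz + m[zero])
        else:
            dl_deta_zero = -w_nb * m[zero]
        dl_deta = dl_deta.copy()
        dl_deta[zero] = dl_deta_zero
        grad[:q] = -(self.X.T @ dl_deta)

        dl_du = np.where(zero, 0.0, -p)
        # d/du log(p + (1-p) q0) = p(1-p)(1-q0) / (p + (1-p) q0)
        q0z = np.exp(log_q0[zero])
        dl_du_zero = p[zero] * (1.0 - p[zero]) * (1.0 - q0z) * np.exp(-ll0)
        dl_du = dl_du.copy()
        dl_du[zero] = dl_du_zero
        grad[q : q + s] = -(self.Z.T @ dl_du)

        if self.has_dispersion:
            dl_dlogr = np.where(zero, 0.0, dl_dlogr_count)
            dl_dlogr = dl_dlogr.copy()
            dl_dlogr[zero] = w_nb * r * (log_r - np.log(r + m[zero]) + m[zero] / (r + m[zero]))
            grad[q + s] = -float(np.sum(dl_dlogr))
        return nll, grad

    def hessian(self, params, rel_step=1e-6):
        """Observed-information Hessian of the negative log-likelihood.

        Central finite differences of the analytic score; symmetrized.
        """
        params = np.asarray(params, dtype=float)
        k = params.size
        H = np.empty((k, k))
        for j in range(k):
            h = rel_step * max(1.0, abs(params[j]))
            pp, pm = params.copy(), params.copy()
            pp[j] += h
            pm[j] -= h
            H[:, j] = (self._nll_grad(pp)[1] - self._nll_grad(pm)[1]) / (2.0 * h)
        return 0.5 * (H + H.T)

    # ------------------------------------------------------------------ #
    # fitting                                                             #
    # ------------------------------------------------------------------ #

    def _poisson_start(self):
        """Count-part start from a quick Poisson fit (or crude log-mean)."""
        ybar = max(self.y.mean(), 1e-3)
        beta0 = np.zeros(self.k_count)
        beta0[0] = np.log(ybar) - self.offset.mean()
        if self.family == "poisson" and not self.is_zi:
            return beta0
        pois = CountModel(
            self.y.astype(int), self.X, offset=self.offset, family="poisson"
        )
        res = optimize.minimize(
            pois._nll_grad, beta0, jac=True, method="L-BFGS-B",
            options={"maxiter": 200},
        )
        return res.x if np.all(np.isfinite(res.x)) else beta0

    def _starts(self):
        beta_p = self._poisson_start()
        starts = []
        base = np.zeros(self.k_params)
        base[: self.k_count] = beta_p
        if self.is_zi:
            m_hat = np.exp(np.clip(self.X @ beta_p + self.offset, -50, 50))
            if self.has_dispersion:
                q0 = np.mean(np.power(1.0 + m_hat, -1.0))
            else:
                q0 = np.mean(np.exp(-m_hat))
            excess = np.clip(np.mean(self._zero_mask) - q0, 0.02, 0.90)
            base[self.k_count] = np.log(excess / (1.0 - excess))
        if self.has_dispersion:
            ybar, yvar = self.y.mean(), self.y.var()
            r0 = ybar**2 / max(yvar - ybar, ybar / 10.0) if ybar > 0 else 1.0
            base[-1] = np.log(np.clip(r0, 1e-3, 1e3))
        starts.append(base)
        starts.append(np.zeros(self.k_params))
        rng = np.random.default_rng(0)  # fixed perturbation, deterministic fits
        starts.append(base + rng.normal(scale=0.5, size=self.k_params))
        return starts

    def _optimize(self, start, maxiter):
        res = optimize.minimize(
            self._nll_grad,
            np.asarray(start, dtype=float),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-6},
        )
        x, nit = res.x, res.nit
        # Newton polish toward a score max-norm well under the convergence
        # criterion.  Steps are capped: in a p -> 0 boundary fit the likelihood
        # is flat in the logit direction and an uncapped Newton step would
        # chase the maximum off to infinity.
        for _ in range(8):
            nll, g = self._nll_grad(x)
            if np.max(np.abs(g)) < 1e-6:
                break
            H = self.hessian(x)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, g, rcond=None)[0]
            if not np.all(np.isfinite(step)):
                break
            big = np.max(np.abs(step))
            if big > 2.0:
                step = step * (2.0 / big)
            lam = 1.0
            for _ in range(30):
                x_new = x - lam * step
                nll_new = self._nll_grad(x_new)[0]
                if np.isfinite(nll_new) and nll_new <= nll + 1e-12:
                    break
                lam *= 0.5
            else:
                break
            x = x_new
            nit += 1
        return x, nit

    def fit(self, start_params=None, maxiter=500, multi_start=True):
        """Maximize the likelihood and return a :class:`CountResults`.

        Non-convergence is flagged on the result, never raised.  Three starts
        (Poisson-initialized, zeros, perturbed) are attempted before giving
        up; ties in likelihood are broken by fewest iterations.
        """
        starts = [np.asarray(start_params, float)] if start_params is not None else []
        if multi_start or not starts:
            starts += self._starts()
        best = None  # (nll, nit, x, converged)
        for s0 in starts:
            try:
                x, nit = self._optimize(s0, maxiter)
                nll, g = self._nll_grad(x)
            except (FloatingPointError, ValueError):
                continue
            if not np.isfinite(nll):
                continue
            conv = bool(np.max(np.abs(g)) < GRAD_TOL)
            cand = (nll, nit, x, conv)
            if best is None or cand[0] < best[0] - 1e-10 or (
                abs(cand[0] - best[0]) <= 1e-10 and cand[1] < best[1]
            ):
                best = cand
            if conv and best is cand:
                break  # first converged best start wins; no need for more
        if best is None:
            x = starts[0]
            return self._make_results(x, converged=False, nit=0)
        nll, nit, x, conv = best
        return self._make_results(x, converged=conv, nit=nit)

    def fit_fixed_infl(self, gamma_fixed, **kwargs):
        """Fit with the zero-part coefficients frozen at ``gamma_fixed``.

        Useful for checking the NB limit of the ZINB (freeze gamma at a very
        negative value).  Frozen coefficients do not count as free parameters.
        """
        if not self.is_zi:
            raise ValueError("fixed zero-part only applies to zero-inflated families")
        gamma_fixed = np.asarray(gamma_fixed, dtype=float)
        sub = _FixedInflModel(self, gamma_fixed)
        res = sub.fit(**kwargs)
        q = self.k_count
        full = np.empty(self.k_params)
        full[:q] = res.params[:q]
        full[q : q + self.k_infl] = gamma_fixed
        if self.has_dispersion:
            full[-1] = res.params[-1]
        out = self._make_results(full, converged=res.converged, nit=res.nit)
        out.n_params = res.n_params
        out.aic = 2.0 * out.n_params - 2.0 * out.llf
        return out

    def _make_results(self, params, converged, nit):
        nll, g = self._nll_grad(params)
        llf = -nll
        beta, gamma, _ = self._split(params)
        boundary = bool(self.k_infl and np.any(np.abs(gamma) > BOUNDARY_LOGIT))
        vcov = None
        if np.all(np.isfinite(params)) and np.isfinite(llf):
            H = self.hessian(params)
            if np.all(np.isfinite(H)):
                try:
                    L = np.linalg.cholesky(H)  # PD check
                    vcov = np.linalg.inv(H)
                except np.linalg.LinAlgError:
                    converged = False
            else:
                converged = False
        else:
            converged = False
        return CountResults(
            model=self,
            params=np.asarray(params, dtype=float),
            llf=float(llf),
            converged=bool(converged),
            boundary_flag=boundary,
            vcov=vcov,
            nit=int(nit),
            grad_norm=float(np.max(np.abs(g))) if np.all(np.isfinite(g)) else np.inf,
        )


class _FixedInflModel(CountModel):
    """Internal: ZI model with the logit part held constant (offset-like)."""

    def __init__(self, parent: CountModel, gamma_fixed):
        # bypass CountModel.__init__; share data, shrink the parameter space
        self.family = parent.family
        self.is_zi = True
        self.has_dispersion = parent.has_dispersion
        self.y = parent.y
        self.X = parent.X
        self.Z = parent.Z
        self.offset = parent.offset
        self.k_count = parent.k_count
        self.k_infl = parent.k_infl
        self.k_params = parent.k_count + int(parent.has_dispersion)
        self.nobs = parent.nobs
        self.param_names = parent.param_names
        self._zero_mask = parent._zero_mask
        self._pos_mask = parent._pos_mask
        self._gamma_fixed = np.asarray(gamma_fixed, dtype=float)
        self._parent = parent

    def _split(self, params):
        beta = params[: self.k_count]
        log_r = params[self.k_count] if self.has_dispersion else None
        return beta, self._gamma_fixed, log_r

    def _nll_grad(self, params):
        full = np.empty(self._parent.k_params)
        full[: self.k_count] = params[: self.k_count]
        full[self.k_count : self.k_count + self.k_infl] = self._gamma_fixed
        if self.has_dispersion:
            full[-1] = params[-1]
        nll, g = self._parent._nll_grad(full)
        grad = np.concatenate(
            [g[: self.k_count], g[-1:] if self.has_dispersion else np.empty(0)]
        )
        return nll, grad

    def _starts(self):
        full_starts = self._parent._starts()
        out = []
        for s in full_starts:
            out.append(
                np.concatenate(
                    [s[: self.k_count], s[-1:] if self.has_dispersion else np.empty(0)]
                )
            )
        return out

    def _make_results(self, params, converged, nit):
        nll, g = self._nll_grad(params)
        res = CountResults(
            model=self,
            params=np.asarray(params, dtype=float),
            llf=float(-nll),
            converged=bool(converged and np.max(np.abs(g)) < GRAD_TOL),
            boundary_flag=False,
            vcov=None,
            nit=int(nit),
            grad_norm=float(np.max(np.abs(g))),
        )
        return res


class CountResults:
    """Fitted count-regression results.

    Attributes include ``params`` (count coefficients, then zero-part
    coefficients, then ``log_r``), ``llf``, ``aic``, ``converged``,
    ``boundary_flag`` (any |logit coefficient| > 20), and ``vcov`` (inverse
    observed information; ``None`` when the information matrix is not
    positive definite).
    """

    def __init__(self, model, params, llf, converged, boundary_flag, vcov, nit, grad_norm):
        self.model = model
        self.params = params
        self.llf = llf
        self.converged = converged
        self.boundary_flag = boundary_flag
        self.vcov = vcov
        self.nit = nit
        self.grad_norm = grad_norm
        self.n_params = model.k_params
        self.aic = 2.0 * self.n_params - 2.0 * llf

    @property
    def count_params(self):
        return self.params[: self.model.k_count]

    @property
    def infl_params(self):
        q = self.model.k_count
        return self.params[q : q + self.model.k_infl]

    @property
    def dispersion_r(self):
        if not self.model.has_dispersion:
            return None
        return float(np.exp(self.params[-1]))

    @property
    def bse(self):
        if self.vcov is None:
            return np.full(self.params.shape, np.nan)
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, np.inf))

    def wald_ci(self, index, level=0.95):
        z = norm.ppf(0.5 + level / 2.0)
        se = self.bse[index]
        est = self.params[index]
        if not np.isfinite(se):
            se = 0.5 * (1.0 + abs(est))
        return ProfileInterval(
            lower=float(est - z * se),
            upper=float(est + z * se),
            level=level,
            method="wald_fallback",
        )

    # ------------------------------------------------------------------ #
    # profile likelihood                                                  #
    # ------------------------------------------------------------------ #

    def _profile_nll(self, index, value, warm):
        """Minimize the negative log-likelihood with params[index] fixed."""
        model = self.model
        free = np.arange(model.k_params) != index
        if not np.any(free):
            full = np.array([value])
            return model._nll_grad(full)[0], warm

        def fun(p_free):
            full = np.empty(model.k_params)
            full[index] = value
            full[free] = p_free
            nll, g = model._nll_grad(full)
            return nll, g[free]

        res = optimize.minimize(
            fun, warm, jac=True, method="L-BFGS-B",
            options={"maxiter": 300, "ftol": 1e-14, "gtol": 1e-10},
        )
        x = res.x
        # short Newton polish on the nuisance block
        full = np.empty(model.k_params)
        full[index] = value
        full[free] = x
        for _ in range(4):
            nll, g = model._nll_grad(full)
            gf = g[free]
            if np.max(np.abs(gf)) < 1e-9:
                break
            H = model.hessian(full)[np.ix_(free, free)]
            try:
                step = np.linalg.solve(H, gf)
            except np.linalg.LinAlgError:
                break
            trial = full.copy()
            lam = 1.0
            ok = False
            for _ in range(20):
                trial[free] = full[free] - lam * step
                nll_new = model._nll_grad(trial)[0]
                if np.isfinite(nll_new) and nll_new <= nll:
                    ok = True
                    break
                lam *= 0.5
            if not ok:
                break
            full = trial.copy()
        return model._nll_grad(full)[0], full[free]

    def profile_ci(self, index, level=0.95, max_expand=60):
        """Profile-likelihood CI for one coefficient.

        Endpoints solve ``2 (llf_max - llf_profile(psi)) = chi2_1(level)``,
        profiling out every other parameter (including the dispersion).  Falls
        back to a Wald interval (``method='wald_fallback'``) if the profile
        machinery fails; a monotone profile yields an infinite endpoint with
        ``unbounded=True``.
        """
        if not (0.0 < level < 1.0):
            raise ValueError("level must be in (0, 1)")
        if not self.converged:
            return self.wald_ci(index, level)
        model = self.model
        est = float(self.params[index])
        crit = chi2.ppf(level, 1)
        se = self.bse[index]
        if not np.isfinite(se) or se <= 0:
            se = 0.2 * (1.0 + abs(est))
        free = np.arange(model.k_params) != index
        warm0 = self.params[free].copy()

        warm_state = {"x": warm0}

        def ratio(value):
            nll, warm = self._profile_nll(index, value, warm_state["x"])
            if np.size(warm):
                warm_state["x"] = np.asarray(warm)
            return 2.0 * (nll - (-self.llf)) - crit

        try:
            bounds = {}
            flags = {}
            for side, sgn in (("lower", -1.0), ("upper", 1.0)):
                warm_state["x"] = warm0.copy()
                delta = se
                inner = est
                r_inner = -crit
                hit = None
                for _ in range(max_expand):
                    psi = est + sgn * delta
                    r_val = ratio(psi)
                    if np.isfinite(r_val) and r_val > 0:
                        hit = (inner, psi) if sgn > 0 else (psi, inner)
                        break
                    if np.isfinite(r_val):
                        inner, r_inner = psi, r_val
                    delta *= 1.7
                if hit is None:
                    bounds[side] = sgn * np.inf
                    flags[side] = True
                    continue
                lo, hi = hit
                root = optimize.brentq(ratio, lo, hi, xtol=1e-6, rtol=8.9e-16)
                bounds[side] = float(root)
                flags[side] = False
            interval = ProfileInterval(
                lower=bounds["lower"],
                upper=bounds["upper"],
                level=level,
                method="profile",
                unbounded=flags["lower"] or flags["upper"],
            )
        except Exception:
            return self.wald_ci(index, level)
        if not (interval.lower <= est <= interval.upper):
            return self.wald_ci(index, level)
        return interval

    # ------------------------------------------------------------------ #

    def to_record(self) -> dict:
        """Flat dict of the fit, suitable for a CSV row."""
        rec = {
            "family": self.model.family,
            "llf": self.llf,
            "aic": self.aic,
            "n_params": self.n_params,
            "converged": self.converged,
            "boundary_flag": self.boundary_flag,
            "dispersion_r": self.dispersion_r,
        }
        for name, val in zip(self.model.param_names, self.params):
            rec[name] = float(val)
        return rec

    def summary(self) -> str:
        lines = [
            f"{self.model.family.upper()} count regression (n={self.model.nobs})",
            f"log-likelihood {self.llf:.4f}   AIC {self.aic:.4f}   "
            f"params {self.n_params}   converged {self.converged}"
            + ("   [boundary]" if self.boundary_flag else ""),
            f"{'term':<16}{'coef':>12}{'std err':>12}",
        ]
        bse = self.bse
        for name, val, se in zip(self.model.param_names, self.params, bse):
            lines.append(f"{name:<16}{val:>12.4f}{se:>12.4f}")
        if self.dispersion_r is not None:
            lines.append(f"dispersion r = {self.dispersion_r:.4f}")
        return "\n".join(lines)


def model_aic(fit: CountResults) -> float:
    """AIC = 2 * n_params - 2 * log-likelihood (every free parameter counted)."""
    if not np.isfinite(fit.llf):
        raise ValueError("AIC undefined: log-likelihood is not finite")
    return 2.0 * fit.n_params - 2.0 * fit.llf


def profile_ci(fit: CountResults, index: int, level: float = 0.95) -> ProfileInterval:
    """Functional alias for :meth:`CountResults.profile_ci`."""
    return fit.profile_ci(index, level=level)
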