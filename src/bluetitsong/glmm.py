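"""Binomial mixed model with a single random intercept.

Maximum-likelihood logistic regression for grouped binomial data

    y_gi ~ Binomial(n_gi, p_gi),   logit(p_gi) = x_gi' beta + sigma * u_g,
    u_g ~ N(0, 1)  i.i.d. per group,

the model family used for both the female-preference and the
habituation/dishabituation analyses (one variance component, "Individual").
The marginal likelihood integrates the group random effect by adaptive
Gauss-Hermite quadrature: for each group the integrand's mode and curvature
are located by Newton steps and the Hermite nodes are recentred and rescaled
there (the lme4 ``nAGQ`` approach), which keeps the quadrature accurate even
for large clusters where the integrand is sharply peaked.

Standard errors are Wald, from a finite-difference Hessian of the marginal
log-likelihood at the optimum; the variance component is optimised on the
log-SD scale for positivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.tools.numdiff import approx_hess1

__all__ = ["BinomialGLMMResult", "fit_binomial_glmm", "check_separation"]

_GH_NODES = 15


@dataclass(frozen=True)
class BinomialGLMMResult:
    """ML fit of a binomial random-intercept model."""

    params: pd.Series  # fixed-effect coefficients (logit scale)
    bse: pd.Series  # Wald standard errors
    conf_int: pd.DataFrame  # columns "low", "high" (95% by default)
    random_sd: float  # random-intercept SD
    random_sd_se: float
    loglik: float
    n_obs: int
    n_groups: int
    n_params: int  # fixed effects + variance component
    converged: bool
    method: str = "ML, adaptive Gauss-Hermite quadrature"
    separation_flag: bool = False

    @property
    def random_var(self) -> float:
        return self.random_sd**2

    def wald_z(self) -> pd.Series:
        return self.params / self.bse


def _group_loglik_terms(
    y: np.ndarray, n: np.ndarray, eta: np.ndarray
) -> np.ndarray:
    # binomial log-kernel; the binomial coefficient is a constant w.r.t. params
    # but is included so loglik values are comparable across models via AICc
    return (
        special.gammaln(n + 1)
        - special.gammaln(y + 1)
        - special.gammaln(n - y + 1)
        + y * eta
        - n * np.logaddexp(0.0, eta)
    )


class _Likelihood:
    def __init__(self, y: np.ndarray, n: np.ndarray, X: np.ndarray, groups: np.ndarray):
        order = np.argsort(groups, kind="stable")
        self.y = y[order].astype(float)
        self.n = n[order].astype(float)
        self.X = X[order]
        g = groups[order]
        _, self.gidx, counts = np.unique(g, return_inverse=True, return_counts=True)
        self.n_groups = counts.size
        nodes, weights = np.polynomial.hermite.hermgauss(_GH_NODES)
        self.gh_x = nodes  # physicists' nodes
        self.log_gh_w = np.log(weights)

    def _mode_and_curvature(self, xb: np.ndarray, sigma: float):
        """Per-group Newton optimisation of h(u) = loglik_g(u) - u^2/2."""
        u = np.zeros(self.n_groups)
        for _ in range(25):
            eta = xb + sigma * u[self.gidx]
            p = special.expit(eta)
            # d/du sum_i [y eta - n log(1+e^eta)] = sigma * sum_i (y - n p)
            score = np.bincount(self.gidx, (self.y - self.n * p) * sigma, self.n_groups) - u
            info = np.bincount(self.gidx, self.n * p * (1 - p) * sigma**2, self.n_groups) + 1.0
            step = score / info
            u = u + np.clip(step, -4.0, 4.0)
            if np.max(np.abs(step)) < 1e-10:
                break
        eta = xb + sigma * u[self.gidx]
        p = special.expit(eta)
        curv = np.bincount(self.gidx, self.n * p * (1 - p) * sigma**2, self.n_groups) + 1.0
        return u, curv

    def loglik(self, theta: np.ndarray) -> float:
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        xb = self.X @ beta
        u_hat, curv = self._mode_and_curvature(xb, sigma)
        tau = 1.0 / np.sqrt(curv)  # per-group quadrature scale
        # L_g = int exp(h_g(u)) phi(u) du, adaptive nodes u = u_hat + sqrt(2) tau x_k
        log_terms = np.empty((self.n_groups, _GH_NODES))
        for k, (xk, logw) in enumerate(zip(self.gh_x, self.log_gh_w)):
            u_k = u_hat + np.sqrt(2.0) * tau * xk
            eta = xb + sigma * u_k[self.gidx]
            ll_obs = _group_loglik_terms(self.y, self.n, eta)
            ll_g = np.bincount(self.gidx, ll_obs, self.n_groups)
            # log[ w_k * sqrt(2) tau * exp(x_k^2) * exp(ll_g) * phi(u_k) ]
            log_terms[:, k] = (
                logw
                + 0.5 * np.log(2.0)
                + np.log(tau)
                + xk**2
                + ll_g
                - 0.5 * u_k**2
                - 0.5 * np.log(2.0 * np.pi)
            )
        return float(special.logsumexp(log_terms, axis=1).sum())


def check_separation(y: np.ndarray, n: np.ndarray) -> bool:
    """Crude complete-separation flag: all successes or all failures."""
    return bool(np.all(y == n) or np.all(y == 0))


def fit_binomial_glmm(
    y,
    n,
    X: pd.DataFrame,
    groups,
    alpha: float = 0.05,
    start_sd: float = 0.5,
) -> BinomialGLMMResult:
    """Fit ``y/n ~ X + (1 | groups)`` by adaptive-quadrature ML.

    Parameters
    ----------
    y, n : successes and trials per row.
    X : design matrix (include an intercept column explicitly).
    groups : grouping labels (the random-intercept unit, e.g. female ID).
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    Xv = np.asarray(X, dtype=float)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(Xv.shape[1])]
    groups = np.asarray(groups)
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("need 0 <= y <= n")
    zero_var = [nm for nm, col in zip(names, Xv.T) if np.ptp(col) == 0 and nm.lower() not in ("intercept", "const")]
    if zero_var:
        raise ValueError(f"zero-variance predictor(s): {zero_var}")
    separation = check_separation(y, n)
    if separation:
        warnings.warn("complete separation: all responses identical; estimates unstable", stacklevel=2)

    lik = _Likelihood(y, n, Xv, groups)

    # start fixed effects from a plain GLM
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(np.column_stack([y, n - y]), Xv, family=sm.families.Binomial()).fit()
    theta0 = np.concatenate([glm.params, [np.log(start_sd)]])

    def nll(theta):
        return -lik.loglik(theta)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            nll, theta0, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
    theta = res.x
    k_fixed = Xv.shape[1]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hess = approx_hess1(theta, nll)
    try:
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(theta.size, np.nan)

    params = pd.Series(theta[:k_fixed], index=names)
    bse = pd.Series(se_all[:k_fixed], index=names)
    zcrit = -special.ndtri(alpha / 2.0)
    ci = pd.DataFrame(
        {"low": params - zcrit * bse, "high": params + zcrit * bse}, index=names
    )
    sigma = float(np.exp(theta[-1]))
    sigma_se = float(sigma * se_all[-1])  # delta method from log-SD scale
    return BinomialGLMMResult(
        params=params,
        bse=bse,
        conf_int=ci,
        random_sd=sigma,
        random_sd_se=sigma_se,
        loglik=float(-res.fun),
        n_obs=int(y.size),
        n_groups=lik.n_groups,
        n_params=k_fixed + 1,
        converged=bool(res.success),
        separation_flag=separation,
    )
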