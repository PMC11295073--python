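"""Random-intercept mixed-model engines.

Gaussian model: y = X b + u_g + e, u_g ~ N(0, s2_b), e ~ N(0, s2_e), fit by
exact maximum likelihood with the variance ratio profiled out — for a single
random-intercept factor the GLS quantities reduce to per-group rank-one
downdates of the OLS cross-products, so each likelihood evaluation is
O(groups * p^2) after one pass over the data.  This makes the within-subject
permutation tests (tens of thousands of refits) tractable; estimates agree
with statsmodels MixedLM(reml=False) to optimizer tolerance.

Binomial model: logistic random-intercept GLMM, marginal likelihood by
Gauss–Hermite quadrature over the group effects, maximized with BFGS.
Maximum likelihood (not REML/PQL) throughout, so likelihood-ratio tests on
fixed effects are valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, logsumexp
from scipy.stats import chi2

__all__ = [
    "MixedFit",
    "fit_lmm_gaussian",
    "fit_glmm_binomial",
    "lrt_pvalue",
]


@dataclass
class MixedFit:
    """One fitted random-intercept model."""

    beta: np.ndarray
    names: list
    loglik: float
    sigma2_e: float | None  # residual variance (gaussian only)
    sigma2_b: float         # random-intercept variance
    n_obs: int
    n_groups: int
    converged: bool
    method: str
    se: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def coef(self, name):
        return float(self.beta[self.names.index(name)])

    def coef_se(self, name):
        return float(self.se[self.names.index(name)])


def _group_codes(groups):
    codes, uniq = np.asarray(groups), None
    _, codes = np.unique(codes, return_inverse=True)
    return codes


class _GaussianProfile:
    """Profiled ML for one design; reusable across variance-ratio values."""

    def __init__(self, y, X, codes):
        self.n, self.p = X.shape
        G = codes.max() + 1
        self.G = G
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        # per-group sums
        self.s = np.zeros((G, self.p))   # X_g' 1
        self.u = np.zeros(G)             # y_g' 1
        np.add.at(self.s, codes, X)
        np.add.at(self.u, codes, y)
        self.ng = np.bincount(codes, minlength=G).astype(float)

    def loglik(self, theta):
        """Profile loglik at variance ratio theta = s2_b / s2_e."""
        w = theta / (1.0 + self.ng * theta)   # per-group downdate weight
        A = self.XtX - (self.s * w[:, None]).T @ self.s
        b = self.Xty - self.s.T @ (w * self.u)
        q = self.yty - float(w @ self.u**2)
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return -np.inf, None, None, None
        rss = q - float(beta @ b)
        if rss <= 0:
            return -np.inf, None, None, None
        s2e = rss / self.n
        ll = (-0.5 * self.n * (np.log(2 * np.pi * s2e) + 1.0)
              - 0.5 * float(np.sum(np.log1p(self.ng * theta))))
        return ll, beta, s2e, A

    def fit(self):
        def neg(logt):
            return -self.loglik(np.exp(logt))[0]

        res = minimize_scalar(neg, bounds=(-12.0, 10.0), method="bounded",
                              options={"xatol": 1e-6})
        ll0 = self.loglik(0.0)[0]
        if ll0 >= -res.fun:
            theta = 0.0
        else:
            theta = float(np.exp(res.x))
        ll, beta, s2e, A = self.loglik(theta)
        if beta is None:
            raise np.linalg.LinAlgError(
                "degenerate gaussian mixed model (singular design or zero "
                "residual variance)")
        cov = s2e * np.linalg.inv(A)
        se = np.sqrt(np.diag(cov))
        return ll, beta, s2e, theta * s2e, se


def fit_lmm_gaussian(y, X, groups, names=None) -> MixedFit:
    """Exact-ML gaussian random-intercept model.

    ``X`` must include the intercept column if one is wanted.  ``groups``
    may be labels of any hashable type.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    codes = _group_codes(groups)
    if codes.max() + 1 < 2:
        raise ValueError("random-intercept fit needs >= 2 groups")
    prof = _GaussianProfile(y, X, codes)
    ll, beta, s2e, s2b, se = prof.fit()
    if not np.isfinite(ll):
        raise np.linalg.LinAlgError("singular design in mixed-model fit")
    return MixedFit(
        beta=beta, names=list(names) if names is not None else
        [f"x{j}" for j in range(X.shape[1])],
        loglik=float(ll), sigma2_e=float(s2e), sigma2_b=float(s2b),
        n_obs=prof.n, n_groups=prof.G, converged=True,
        method="profiled-ML", se=se,
    )


def _bern_loglik(lin, y):
    s = np.where(y > 0.5, 1.0, -1.0)
    return -np.logaddexp(0.0, -s * lin)


def _glmm_negloglik(params, y, X, group_rows, nodes, weights):
    """Adaptive Gauss–Hermite marginal negative loglik.

    Quadrature nodes are recentered on each group's conditional mode and
    rescaled by the curvature there (the integrand is far too peaked for
    fixed nodes once groups hold more than a handful of trials).
    """
    p = X.shape[1]
    beta = params[:p]
    sigma = np.exp(params[p])
    s2 = sigma * sigma
    eta = X @ beta
    total = 0.0
    for rows in group_rows:
        e = eta[rows]
        yg = y[rows]
        # 1D Newton for the conditional mode of the group effect
        u = 0.0
        for _ in range(50):
            mu = expit(e + u)
            g = float(np.sum(yg - mu)) - u / s2
            h = float(np.sum(mu * (1 - mu))) + 1.0 / s2
            step = g / h
            u += step
            if abs(step) < 1e-10:
                break
        mu = expit(e + u)
        h = float(np.sum(mu * (1 - mu))) + 1.0 / s2
        tau = 1.0 / np.sqrt(h)
        uq = u + np.sqrt(2.0) * tau * nodes                      # (Q,)
        f = (_bern_loglik(e[None, :] + uq[:, None], yg[None, :]).sum(axis=1)
             - 0.5 * uq**2 / s2 - 0.5 * np.log(2 * np.pi * s2))
        total += (logsumexp(np.log(weights) + nodes**2 + f)
                  + 0.5 * np.log(2.0) + np.log(tau))
    return -total


def fit_glmm_binomial(y, X, groups, names=None, n_quad=25,
                      start=None) -> MixedFit:
    """ML logistic random-intercept GLMM via Gauss–Hermite quadrature.

    The marginal likelihood integrates the participant effects over
    ``n_quad`` Hermite nodes; (fixed effects, log sigma_b) are maximized
    with BFGS from a logistic-regression start.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    codes = _group_codes(groups)
    G = codes.max() + 1
    if G < 2:
        raise ValueError("random-intercept fit needs >= 2 groups")
    group_rows = [np.flatnonzero(codes == g) for g in range(G)]
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)

    if start is None:
        # plain logistic regression start (few Newton steps, ridge-guarded)
        beta0 = np.zeros(X.shape[1])
        for _ in range(25):
            mu = expit(X @ beta0)
            W = mu * (1 - mu) + 1e-6
            H = (X * W[:, None]).T @ X + 1e-8 * np.eye(X.shape[1])
            g = X.T @ (y - mu)
            step = np.linalg.solve(H, g)
            beta0 = beta0 + step
            if np.abs(step).max() < 1e-8:
                break
        beta0 = np.clip(beta0, -15, 15)
        start = np.concatenate([beta0, [np.log(0.5)]])

    args = (y, X, group_rows, nodes, weights)
    res = minimize(_glmm_negloglik, start, args=args,
                   method="BFGS", options={"gtol": 1e-6, "maxiter": 500})
    if not res.success:
        polish = minimize(_glmm_negloglik, res.x, args=args,
                          method="Nelder-Mead",
                          options={"xatol": 1e-8, "fatol": 1e-10,
                                   "maxiter": 2000})
        if polish.fun <= res.fun:
            polish.hess_inv = res.hess_inv
            res = polish
    p = X.shape[1]
    beta = res.x[:p]
    sigma = float(np.exp(res.x[p]))
    se = None
    if res.hess_inv is not None:
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.abs(np.diag(np.atleast_2d(res.hess_inv))))[:p]
    return MixedFit(
        beta=beta, names=list(names) if names is not None else
        [f"x{j}" for j in range(p)],
        loglik=-float(res.fun), sigma2_e=None, sigma2_b=sigma**2,
        n_obs=len(y), n_groups=G,
        converged=bool(res.success) and bool(np.abs(beta).max() < 15),
        method=f"gauss-hermite({n_quad})-ML", se=se,
        extra={"optimizer_message": str(res.message)},
    )


def lrt_pvalue(ll_full, ll_reduced, df=1):
    """Likelihood-ratio test of nested ML fits; statistic floored at 0."""
    stat = max(0.0, 2.0 * (ll_full - ll_reduced))
    return stat, float(chi2.sf(stat, df))
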