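"""Numerical engines for the mixed-effects models.

Two estimators live here, both with a single random intercept per
participant:

* a Gaussian linear mixed model whose residual variance follows
  ``Var(e_ij) = sigma^2 * delta_{g(i)}^2 / w_ij`` — a per-stratum
  multiplier (one stratum fixed to 1, the analogue of nlme's ``varIdent``)
  combined with inverse observation weights (``varFixed``).  The random
  intercept ratio and the multipliers are profiled out of the (restricted)
  likelihood and optimised numerically; beta and sigma^2 have closed forms
  given them.

* a Poisson log-link GLMM, fitted by maximising an adaptive Gauss-Hermite
  approximation of the marginal likelihood (the random-intercept integral
  is one-dimensional, so the quadrature is cheap and accurate).

statsmodels offers neither (MixedLM has a single homoscedastic residual
variance; there is no frequentist GLMM), which is why the engines are
written out here; statsmodels and R's nlme/lme4 serve as cross-checks in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import gammaln, logsumexp

__all__ = ["GaussianLMMFit", "fit_gaussian_lmm", "PoissonGLMMFit", "fit_poisson_glmm"]

_LOG2PI = np.log(2.0 * np.pi)


def _group_indices(groups) -> list[np.ndarray]:
    groups = np.asarray(groups)
    order = np.argsort(groups, kind="stable")
    uniq, starts = np.unique(groups[order], return_index=True)
    bounds = np.append(starts, groups.size)
    return [order[bounds[k]:bounds[k + 1]] for k in range(uniq.size)]


@dataclass
class GaussianLMMFit:
    """Fitted Gaussian LMM with random intercept and structured residuals."""

    beta: np.ndarray
    cov_beta: np.ndarray
    names: list[str]
    sigma2: float          # residual variance of the reference stratum at weight 1
    re_var: float          # random-intercept variance
    deltas: dict           # stratum -> residual SD multiplier (reference = 1)
    loglik: float
    method: str            # 'reml' or 'ml'
    nobs: int
    rank: int
    n_vc: int              # variance parameters optimised numerically
    converged: bool

    @property
    def df_resid(self) -> float:
        return self.nobs - self.rank

    @property
    def n_params(self) -> int:
        # fixed effects + sigma2 + numerically optimised variance parameters
        return self.rank + 1 + self.n_vc

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params


def fit_gaussian_lmm(y, X, groups, var_strata=None, weights=None, reml: bool = True,
                     names=None) -> GaussianLMMFit:
    """Fit the random-intercept LMM with the combined variance structure.

    Parameters
    ----------
    y, X
        Response vector and fixed-effects design matrix.
    groups
        Random-intercept grouping labels, one per observation.
    var_strata
        Optional per-observation stratum labels for the residual-SD
        multipliers; the first stratum in sorted order is the reference
        (multiplier 1).  With a single stratum the structure collapses.
    weights
        Optional positive observation weights; residual variance scales
        with 1/weight.
    reml
        Restricted (True, for reported estimates) or full maximum
        likelihood (False, for likelihood-ratio tests and AIC comparisons
        of fixed effects).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y and X have incompatible shapes")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effects design is rank deficient")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")

    if var_strata is None:
        strata_levels = []
        strata_codes = np.zeros(n, dtype=int)
    else:
        arr = np.asarray(var_strata)
        strata_levels = sorted(set(arr.tolist()))
        lookup = {s: k for k, s in enumerate(strata_levels)}
        strata_codes = np.array([lookup[s] for s in arr])
    n_delta = max(len(strata_levels) - 1, 0)

    # sort observations by group so per-group sums become reduceat calls
    order = np.argsort(np.asarray(groups), kind="stable")
    Xs, ys, ws, ss = X[order], y[order], w[order], strata_codes[order]
    gsorted = np.asarray(groups)[order]
    starts = np.flatnonzero(np.r_[True, gsorted[1:] != gsorted[:-1]])

    def decompose(theta):
        theta = np.clip(theta, -12.0, 12.0)
        tau2 = np.exp(2.0 * theta[0])
        mult = np.concatenate([[1.0], np.exp(theta[1:])]) if n_delta else np.array([1.0])
        return tau2, mult

    def profile(theta):
        """Profiled quantities at variance parameters theta."""
        tau2, mult = decompose(theta)
        d = mult[ss] ** 2 / ws
        u = 1.0 / d
        uX = u[:, None] * Xs
        uy = u * ys
        su = np.add.reduceat(u, starts)              # per-group sum of 1/d
        k = tau2 / (1.0 + tau2 * su)
        cX = np.add.reduceat(uX, starts, axis=0)     # per-group X' D^-1 1
        cy = np.add.reduceat(uy, starts)
        XtViX = Xs.T @ uX - (cX * k[:, None]).T @ cX
        XtViy = uX.T @ ys - (cX * k[:, None]).T @ cy
        yViy = ys @ uy - k @ (cy * cy)
        logdet = np.log(d).sum() + np.log1p(tau2 * su).sum()
        beta = np.linalg.solve(XtViX, XtViy)
        rss = max(yViy - beta @ XtViy, 1e-12)
        return beta, rss, logdet, XtViX

    def nll(theta):
        _, rss, logdet, XtViX = profile(theta)
        if reml:
            df = n - p
            s2 = rss / df
            _, ld2 = np.linalg.slogdet(XtViX)
            return 0.5 * (df * (_LOG2PI + np.log(s2) + 1.0) + logdet + ld2)
        s2 = rss / n
        return 0.5 * (n * (_LOG2PI + np.log(s2) + 1.0) + logdet)

    theta0 = np.zeros(1 + n_delta)
    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 4000})
    theta = res.x
    tau2, mult = decompose(theta)
    beta, rss, logdet, XtViX = profile(theta)
    s2 = rss / (n - p) if reml else rss / n
    cov_beta = s2 * np.linalg.inv(XtViX)
    deltas = {s: float(mult[k]) for k, s in enumerate(strata_levels)} if strata_levels else {}

    # --- Satterthwaite machinery -----------------------------------------
    # Unprofiled variance parameterisation phi = (log tau, log deltas...,
    # log sigma2); the REML criterion in phi yields the asymptotic
    # covariance of the variance parameters, and the delta method on
    # f(phi) = Var(L' beta_hat) gives the denominator df of a contrast.
    phi_hat = np.append(np.clip(theta, -12.0, 12.0), np.log(s2))

    def _pieces(phi):
        ltau = phi[0]
        lsig = phi[-1]
        sig2 = np.exp(lsig)
        a = sig2 * np.exp(2.0 * ltau)                      # random-intercept var
        m2 = np.concatenate([[1.0], np.exp(phi[1:-1])]) if n_delta else np.array([1.0])
        d = sig2 * m2[ss] ** 2 / ws
        u = 1.0 / d
        su = np.add.reduceat(u, starts)
        k = a / (1.0 + a * su)
        uX = u[:, None] * Xs
        cX = np.add.reduceat(uX, starts, axis=0)
        XtViX_ = Xs.T @ uX - (cX * k[:, None]).T @ cX
        uy = u * ys
        cy = np.add.reduceat(uy, starts)
        XtViy_ = uX.T @ ys - (cX * k[:, None]).T @ cy
        yViy_ = ys @ uy - k @ (cy * cy)
        logdet_ = np.log(d).sum() + np.log1p(a * su).sum()
        return XtViX_, XtViy_, yViy_, logdet_

    def reml_crit(phi):
        XtViX_, XtViy_, yViy_, logdet_ = _pieces(phi)
        b = np.linalg.solve(XtViX_, XtViy_)
        rss_ = yViy_ - b @ XtViy_
        _, ld2 = np.linalg.slogdet(XtViX_)
        return 0.5 * ((n - p) * _LOG2PI + logdet_ + ld2 + rss_)

    def contrast_var(phi, L):
        XtViX_, _, _, _ = _pieces(phi)
        return float(L @ np.linalg.solve(XtViX_, L))

    from statsmodels.tools.numdiff import approx_hess1

    _cov_phi_cache: list = []

    def contrast_df(L) -> float:
        """Satterthwaite denominator df for the scalar contrast L' beta."""
        if not _cov_phi_cache:
            H = approx_hess1(phi_hat, reml_crit)
            try:
                _cov_phi_cache.append(np.linalg.inv(H))
            except np.linalg.LinAlgError:
                _cov_phi_cache.append(np.linalg.pinv(H))
        cov_phi = _cov_phi_cache[0]
        L = np.asarray(L, dtype=float)
        f0 = contrast_var(phi_hat, L)
        eps = 1e-4
        grad = np.zeros(phi_hat.size)
        for j in range(phi_hat.size):
            up = phi_hat.copy(); up[j] += eps
            dn = phi_hat.copy(); dn[j] -= eps
            grad[j] = (contrast_var(up, L) - contrast_var(dn, L)) / (2.0 * eps)
        denom = float(grad @ cov_phi @ grad)
        if denom <= 0:
            return float(n - p)
        return float(np.clip(2.0 * f0 * f0 / denom, 1.0, n - p))

    fit = GaussianLMMFit(
        beta=beta,
        cov_beta=cov_beta,
        names=list(names) if names is not None else [f"x{j}" for j in range(p)],
        sigma2=float(s2),
        re_var=float(tau2 * s2),
        deltas=deltas,
        loglik=float(-res.fun),
        method="reml" if reml else "ml",
        nobs=n,
        rank=p,
        n_vc=1 + n_delta,
        converged=bool(res.success),
    )
    fit.contrast_df = contrast_df
    return fit


@dataclass
class PoissonGLMMFit:
    """Fitted Poisson log-link GLMM with a random intercept."""

    beta: np.ndarray
    cov_beta: np.ndarray
    names: list[str]
    re_var: float
    loglik: float
    nobs: int
    rank: int
    converged: bool
    n_quad: int

    @property
    def df_resid(self) -> float:
        return self.nobs - self.rank

    @property
    def n_params(self) -> int:
        return self.rank + 1

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params


def fit_poisson_glmm(y, X, groups, n_quad: int = 15, names=None) -> PoissonGLMMFit:
    """Maximum-likelihood Poisson GLMM via adaptive Gauss-Hermite quadrature."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("Poisson responses must be nonnegative integers")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effects design is rank deficient")

    idx = _group_indices(groups)
    G = len(idx)
    const = -gammaln(y + 1.0).sum()
    nodes, wts = hermgauss(n_quad)
    log_wts = np.log(wts)

    ysum = np.array([y[i].sum() for i in idx])

    def nll(params):
        beta = params[:p]
        sigma = np.exp(np.clip(params[p], -8.0, 4.0))
        eta = X @ beta
        mu_terms = np.array([np.exp(eta[i]).sum() for i in idx])      # E_g
        yeta = np.array([(y[i] * eta[i]).sum() for i in idx])          # sum y*eta
        s2 = sigma * sigma

        # Newton for the per-group posterior mode of b
        b = np.zeros(G)
        for _ in range(50):
            eb = np.exp(b)
            g1 = ysum - eb * mu_terms - b / s2
            g2 = -eb * mu_terms - 1.0 / s2
            step = g1 / g2
            b -= step
            if np.max(np.abs(step)) < 1e-10:
                break
        eb = np.exp(b)
        h2 = eb * mu_terms + 1.0 / s2          # -h''(b_hat)
        s_lap = 1.0 / np.sqrt(h2)

        # h(b) = yeta + ysum*b - e^b * E - b^2/(2 s2) - log(sqrt(2 pi) sigma)
        bk = b[:, None] + np.sqrt(2.0) * s_lap[:, None] * nodes[None, :]
        hk = (yeta[:, None] + ysum[:, None] * bk - np.exp(bk) * mu_terms[:, None]
              - bk * bk / (2.0 * s2)) - 0.5 * np.log(2.0 * np.pi * s2)
        lg = logsumexp(hk + nodes[None, :] ** 2 + log_wts[None, :], axis=1)
        ll = const + np.sum(lg + 0.5 * np.log(2.0 * s_lap ** 2))
        return -ll

    # start from the fixed-effects Poisson GLM
    from statsmodels.api import GLM, families

    glm = GLM(y, X, family=families.Poisson()).fit()
    x0 = np.concatenate([glm.params, [np.log(0.5)]])
    res = optimize.minimize(nll, x0, method="BFGS",
                            options={"gtol": 1e-7, "maxiter": 500})
    from statsmodels.tools.numdiff import approx_hess1

    hess = approx_hess1(res.x, nll)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    sigma = float(np.exp(np.clip(res.x[p], -8.0, 4.0)))
    return PoissonGLMMFit(
        beta=res.x[:p],
        cov_beta=cov[:p, :p],
        names=list(names) if names is not None else [f"x{j}" for j in range(p)],
        re_var=sigma * sigma,
        loglik=float(-res.fun),
        nobs=n,
        rank=p,
        converged=bool(res.success),
        n_quad=n_quad,
    )
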