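"""Lightweight REML engine for linear mixed models with grouped random effects.

Model: y = X b + sum_i Z_i u_i + e, with u_i ~ N(0, s2 * G) per group i and
e ~ N(0, s2 * I).  G is diagonal, parametrized by log standard-deviation
ratios.  The residual variance and fixed effects are profiled out, so one
objective evaluation costs only O(n_groups * q^3) after a single pass over
the data to accumulate per-group cross-products — independent of the number
of rows.  Group computations are batched and the restricted-likelihood
gradient is analytic, which makes the thousands of refits required by the
hierarchical bootstrap affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

_LOG_LAMBDA_BOUNDS = (-8.0, 4.0)


class LMMError(RuntimeError):
    pass


@dataclass
class LMMResult:
    beta: np.ndarray
    se_beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    lambdas: np.ndarray      # random-effect SDs as multiples of sigma
    theta: np.ndarray        # log(lambdas), optimizer coordinates
    reml_deviance: float     # -2 * restricted log-likelihood
    converged: bool
    n: int
    p: int

    @property
    def n_params(self) -> int:
        """Free parameters: fixed effects + variance ratios + residual."""
        return self.p + len(self.lambdas) + 1

    def re_sd(self) -> np.ndarray:
        return self.lambdas * np.sqrt(self.sigma2)


class _SuffStats:
    """Stacked per-group cross-products; all the REML criterion needs."""

    def __init__(self, y, X, Z, groups):
        y = np.ascontiguousarray(y, dtype=float)
        X = np.ascontiguousarray(X, dtype=float)
        Z = np.ascontiguousarray(Z, dtype=float)
        if y.ndim != 1 or X.shape[0] != y.size or Z.shape[0] != y.size:
            raise LMMError("inconsistent row counts")
        self.n, self.p = X.shape
        self.q = Z.shape[1]
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        codes = np.unique(np.asarray(groups), return_inverse=True)[1]
        order = np.argsort(codes, kind="stable")
        bounds = np.flatnonzero(np.diff(codes[order])) + 1
        S, ZtX, Zty = [], [], []
        for idx in np.split(order, bounds):
            Zi, Xi, yi = Z[idx], X[idx], y[idx]
            S.append(Zi.T @ Zi)
            ZtX.append(Zi.T @ Xi)
            Zty.append(Zi.T @ yi)
        self.S = np.stack(S)          # (g, q, q)
        self.ZtX = np.stack(ZtX)      # (g, q, p)
        self.Zty = np.stack(Zty)      # (g, q)
        self.n_groups = self.S.shape[0]
        self.S_diag_sum = self.S.diagonal(axis1=1, axis2=2).sum(axis=0)


def _criterion(theta, st: _SuffStats, want: str = "grad"):
    """Profiled REML deviance, optionally with its analytic gradient or the
    full parameter estimates (``want`` in {"dev", "grad", "full"})."""
    lam = np.exp(np.clip(theta, *_LOG_LAMBDA_BOUNDS))
    M = (lam[:, None] * st.S) * lam[None, :]
    idx = np.arange(st.q)
    M[:, idx, idx] += 1.0
    try:
        chol = np.linalg.cholesky(M)
    except np.linalg.LinAlgError as exc:
        raise LMMError("singular random-effects system") from exc
    logdet = 2.0 * np.sum(np.log(chol.diagonal(axis1=1, axis2=2)))
    WX = lam[None, :, None] * st.ZtX            # (g, q, p)
    Wy = lam[None, :] * st.Zty                  # (g, q)
    rhs = np.concatenate([WX, Wy[:, :, None]], axis=2)
    sol = np.linalg.solve(M, rhs)
    MiWX, MiWy = sol[:, :, :-1], sol[:, :, -1]
    XtVX = st.XtX - np.einsum("gqp,gqr->pr", WX, MiWX)
    XtVy = st.Xty - np.einsum("gqp,gq->p", WX, MiWy)
    ytVy = st.yty - float(np.einsum("gq,gq->", Wy, MiWy))
    try:
        cX = cho_factor(XtVX, lower=True)
    except np.linalg.LinAlgError as exc:
        raise LMMError("singular fixed-effects system") from exc
    beta = cho_solve(cX, XtVy)
    rss = max(ytVy - float(beta @ XtVy), 1e-300)
    dfe = st.n - st.p
    sigma2 = rss / dfe
    logdet_XtVX = 2.0 * np.sum(np.log(np.diag(cX[0])))
    dev = dfe * (1.0 + np.log(2.0 * np.pi * sigma2)) + logdet + logdet_XtVX
    if want == "dev":
        return dev
    if want == "full":
        cov_beta = sigma2 * cho_solve(cX, np.eye(st.p))
        return dev, beta, sigma2, cov_beta, lam

    # analytic gradient wrt theta_j = log(lambda_j):
    #   dD/dtheta_j = 2 lam_j^2 [ sum_i T_i,jj - sum_i (A_i' C^-1 A_i)_jj
    #                             - sum_i b_ij^2 / sigma2 ]
    # with T_i = Z_i' V_i^-1 Z_i, A_i = Z_i' V_i^-1 X_i, b_i = Z_i' P y.
    G = lam[None, :, None] * st.S               # G_i = Lam S_i, (g, q, q)
    MiG = np.linalg.solve(M, G)
    T_diag = st.S_diag_sum - np.einsum("gkj,gkj->j", G, MiG)
    A = st.ZtX - np.einsum("gkq,gkp->gqp", G, MiWX)
    A2 = A.reshape(-1, st.p)
    CiA = cho_solve(cX, A2.T)                   # (p, g*q)
    ACA_diag = (A2 * CiA.T).sum(axis=1).reshape(st.n_groups, st.q).sum(axis=0)
    b = st.Zty - np.einsum("gkq,gk->gq", G, MiWy) - A @ beta
    grad = 2.0 * lam ** 2 * (T_diag - ACA_diag - (b ** 2).sum(axis=0) / sigma2)
    return dev, grad


def reml_fit(y, X, Z, groups, start: np.ndarray | None = None,
             maxiter: int = 500, tol: float = 1e-8) -> LMMResult:
    """REML fit with diagonal random-effect covariance.

    Parameters
    ----------
    y, X : response vector and fixed-effects design.
    Z : random-effects design, same rows as X; columns define per-group
        random coefficients with independent variances.
    groups : group label per row.
    start : optional warm start for the log SD-ratio parameters (e.g. the
        estimate from a fit to the un-resampled data).
    """
    st = _SuffStats(y, X, Z, groups)
    theta0 = np.full(st.q, -0.5) if start is None else np.asarray(start, float)

    def obj(theta):
        try:
            return _criterion(theta, st, want="grad")
        except LMMError:
            return 1e12, np.zeros_like(theta)

    res = optimize.minimize(
        obj, theta0, jac=True, method="L-BFGS-B",
        bounds=[_LOG_LAMBDA_BOUNDS] * st.q,
        options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-7})
    dev, beta, sigma2, cov_beta, lam = _criterion(res.x, st, want="full")
    se = np.sqrt(np.diag(cov_beta))
    return LMMResult(beta=beta, se_beta=se, cov_beta=cov_beta, sigma2=sigma2,
                     lambdas=lam, theta=res.x, reml_deviance=float(dev),
                     converged=bool(res.success), n=st.n, p=st.p)
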