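"""Profiled-REML linear mixed model with a single random intercept.

The model is ``y = X beta + Z b + e`` with one random intercept per group
(``b ~ N(0, tau2)``, ``e ~ N(0, sigma2)``).  The restricted likelihood is
profiled over the variance ratio ``lambda = tau2 / sigma2``: for fixed
lambda both ``beta`` (by GLS) and ``sigma2`` (in closed form with the REML
denominator N - p) are available analytically, leaving a 1-D criterion in
lambda that is scanned on a log-spaced grid and refined by bounded
optimization.  The lambda = 0 boundary (no between-group variance) is
always a candidate; boundary fits are legitimate results, not errors.

All block computations use the Woodbury identity per group, so the cost is
linear in the number of observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass
class RandomInterceptFit:
    beta: np.ndarray
    cov_beta: np.ndarray  # sigma2 * (X' V0^-1 X)^-1
    tau2: float
    sigma2: float
    groups: np.ndarray  # unique group labels
    n_obs: int
    converged: bool = True

    def wald(self, contrast) -> tuple:
        """Wald z-test of ``contrast @ beta = 0``; returns (est, se, z, p)."""
        c = np.asarray(contrast, dtype=float)
        est = float(c @ self.beta)
        se = float(np.sqrt(c @ self.cov_beta @ c))
        if se == 0 or not np.isfinite(se):
            return est, se, np.nan, np.nan
        z = est / se
        return est, se, float(z), float(2.0 * stats.norm.sf(abs(z)))


def _prepare_blocks(y, groups, X):
    glabels, ginv = np.unique(groups, return_inverse=True)
    blocks = []
    for g in range(len(glabels)):
        idx = np.nonzero(ginv == g)[0]
        Xi = X[idx]
        yi = y[idx]
        blocks.append(
            (
                len(idx),
                Xi.T @ Xi,
                Xi.sum(axis=0),
                Xi.T @ yi,
                float(yi.sum()),
                float(yi @ yi),
            )
        )
    return glabels, blocks


def _profile(lam, blocks, N, p):
    """For fixed variance ratio lam: beta_hat, sigma2_hat and REML criterion."""
    A = np.zeros((p, p))
    b = np.zeros(p)
    yty = 0.0
    logdetV0 = 0.0
    for n_i, XtX, Xt1, Xty, ysum, yy in blocks:
        c = lam / (1.0 + lam * n_i)
        A += XtX - c * np.outer(Xt1, Xt1)
        b += Xty - c * ysum * Xt1
        yty += yy - c * ysum**2
        logdetV0 += np.log1p(lam * n_i)
    beta = np.linalg.solve(A, b)
    rss = max(yty - b @ beta, 0.0)
    dof = N - p
    sigma2 = rss / dof
    if sigma2 <= 0:
        return beta, 0.0, A, -np.inf if rss == 0 else np.inf
    sign, logdetA = np.linalg.slogdet(A)
    crit = logdetV0 + dof * np.log(sigma2) + logdetA
    return beta, sigma2, A, crit


def fit_random_intercept_lmm(y, groups, X=None) -> RandomInterceptFit:
    """Fit ``y = X beta + (1 | group) + e`` by profiled REML.

    Parameters
    ----------
    y : array-like
        Response vector.
    groups : array-like
        Group label per observation (the random-intercept factor).
    X : array-like, optional
        Fixed-effects design matrix; defaults to an intercept column.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    N = y.size
    if N < 2:
        raise ValueError("need at least 2 observations")
    if X is None:
        X = np.ones((N, 1))
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if N <= p:
        raise ValueError("more parameters than observations")
    glabels, blocks = _prepare_blocks(y, groups, X)

    if np.ptp(y) == 0.0:
        warnings.warn("degenerate fit: response is constant")
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        return RandomInterceptFit(
            beta=beta,
            cov_beta=np.zeros((p, p)),
            tau2=0.0,
            sigma2=0.0,
            groups=glabels,
            n_obs=N,
            converged=True,
        )

    if len(glabels) == 1:
        # between-group variance unidentifiable with one group
        beta, sigma2, A, _ = _profile(0.0, blocks, N, p)
        return RandomInterceptFit(
            beta=beta,
            cov_beta=sigma2 * np.linalg.inv(A),
            tau2=0.0,
            sigma2=float(sigma2),
            groups=glabels,
            n_obs=N,
        )

    grid = np.concatenate([[0.0], np.geomspace(1e-8, 1e6, 100)])
    crits = np.array([_profile(lam, blocks, N, p)[3] for lam in grid])
    i = int(np.nanargmin(crits))
    lam_best = grid[i]
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda lam: _profile(lam, blocks, N, p)[3],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if res.fun <= crits[i]:
            lam_best = float(res.x)
    if _profile(0.0, blocks, N, p)[3] <= _profile(lam_best, blocks, N, p)[3]:
        lam_best = 0.0

    beta, sigma2, A, _ = _profile(lam_best, blocks, N, p)
    tau2 = lam_best * sigma2
    cov_beta = sigma2 * np.linalg.inv(A)
    return RandomInterceptFit(
        beta=beta,
        cov_beta=cov_beta,
        tau2=float(tau2),
        sigma2=float(sigma2),
        groups=glabels,
        n_obs=N,
    )
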