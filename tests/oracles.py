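"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's own profiled/optimized code paths:
the REML criteria are evaluated from explicit per-group covariance blocks,
and optima are located by dense grid search with local refinement.
"""

import itertools

import numpy as np
from scipy import stats


def reml_pool_criterion(tau2, g, v):
    """-2 x restricted log-likelihood (constant dropped) for known-variance
    random-effects pooling."""
    w = 1.0 / (v + tau2)
    mu = (w * g).sum() / w.sum()
    return np.log(v + tau2).sum() + np.log(w.sum()) + (w * (g - mu) ** 2).sum()


def reml_pool_grid_oracle(g, v, hi=None, n_coarse=2001, n_refine=2001):
    """Grid search for the REML tau2, refined twice around the minimum."""
    g = np.asarray(g, dtype=float)
    v = np.asarray(v, dtype=float)
    if hi is None:
        hi = max(5.0, 10.0 * g.var(ddof=0))
    grid = np.linspace(0.0, hi, n_coarse)
    vals = [reml_pool_criterion(t, g, v) for t in grid]
    i = int(np.argmin(vals))
    for _ in range(2):
        lo = grid[max(i - 1, 0)]
        up = grid[min(i + 1, len(grid) - 1)]
        grid = np.linspace(lo, up, n_refine)
        vals = [reml_pool_criterion(t, g, v) for t in grid]
        i = int(np.argmin(vals))
    tau2 = float(grid[i])
    w = 1.0 / (v + tau2)
    mu = float((w * g).sum() / w.sum())
    return mu, tau2


def lmm_reml_criterion(tau2, sigma2, y, groups, X=None):
    """-2 x restricted log-likelihood from explicit block covariance matrices."""
    y = np.asarray(y, dtype=float)
    if X is None:
        X = np.ones((y.size, 1))
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    A = np.zeros((p, p))
    b = np.zeros(p)
    logdetV = 0.0
    blocks = []
    for gl in np.unique(groups):
        idx = np.asarray(groups) == gl
        yi, Xi = y[idx], X[idx]
        n = yi.size
        V = sigma2 * np.eye(n) + tau2 * np.ones((n, n))
        Vi = np.linalg.inv(V)
        sign, ld = np.linalg.slogdet(V)
        logdetV += ld
        A += Xi.T @ Vi @ Xi
        b += Xi.T @ Vi @ yi
        blocks.append((yi, Xi, Vi))
    beta = np.linalg.solve(A, b)
    quad = sum(
        float((yi - Xi @ beta) @ Vi @ (yi - Xi @ beta)) for yi, Xi, Vi in blocks
    )
    sign, logdetA = np.linalg.slogdet(A)
    return logdetV + logdetA + quad, beta


def _lmm_criterion_grid(tau2s, sigma2s, n_i, ybar_i, ss_i):
    """-2 x restricted log-likelihood of the intercept-only model on a
    (tau2, sigma2) grid, from per-group sufficient statistics.

    For groups i with n_i observations, mean ybar_i and within-group sum of
    squares ss_i:

        crit = sum_i [(n_i - 1) log s2 + log(s2 + n_i t2)] + sum_i ss_i / s2
             + sum_i n_i (ybar_i - mu)^2 / (s2 + n_i t2) + log sum_i w_i

    with w_i = n_i / (s2 + n_i t2) and mu the w-weighted mean of ybar_i.
    """
    t2 = tau2s[:, None, None]
    s2 = sigma2s[None, :, None]
    n = n_i[None, None, :]
    vb = s2 + n * t2  # variance of each group mean x n
    w = n / vb
    mu = (w * ybar_i[None, None, :]).sum(axis=2) / w.sum(axis=2)
    dev = ybar_i[None, None, :] - mu[:, :, None]
    crit = (
        ((n - 1) * np.log(s2)).sum(axis=2)
        + np.log(vb).sum(axis=2)
        + ss_i.sum() / sigma2s[None, :]
        + (w * dev**2).sum(axis=2)
        + np.log(w.sum(axis=2))
    )
    mu_grid = mu
    return crit, mu_grid


def lmm_grid_oracle(y, groups, n_grid=200, n_zoom=3):
    """Brute-force restricted-likelihood grid search over (tau2, sigma2)
    for the intercept-only random-intercept model, with iterative zooming
    around the grid minimum."""
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    glabels = np.unique(groups)
    n_i = np.array([(groups == g).sum() for g in glabels], dtype=float)
    ybar_i = np.array([y[groups == g].mean() for g in glabels])
    ss_i = np.array([((y[groups == g] - yb) ** 2).sum() for g, yb in zip(glabels, ybar_i)])

    s2_pool = max(ss_i.sum() / max(y.size - len(glabels), 1), 1e-8)
    t2_hi = max(10.0 * ybar_i.var(), 10.0 * s2_pool, 1e-6)
    tau2s = np.concatenate([[0.0], np.geomspace(t2_hi * 1e-8, t2_hi, n_grid)])
    sigma2s = np.geomspace(s2_pool / 30, s2_pool * 30, n_grid)
    best = None
    # zoom window spans several grid steps: the criterion valley runs
    # diagonally in (tau2, sigma2) and a one-step window can trap the search
    w = 8
    for _ in range(1 + n_zoom):
        crit, mu_grid = _lmm_criterion_grid(tau2s, sigma2s, n_i, ybar_i, ss_i)
        i, j = np.unravel_index(np.argmin(crit), crit.shape)
        best = (float(mu_grid[i, j]), float(tau2s[i]), float(sigma2s[j]))
        t_lo = tau2s[max(i - w, 0)]
        t_hi = tau2s[min(i + w, len(tau2s) - 1)]
        s_lo = sigma2s[max(j - w, 0)]
        s_hi = sigma2s[min(j + w, len(sigma2s) - 1)]
        tau2s = np.linspace(t_lo, max(t_hi, t_lo + 1e-12), n_grid)
        sigma2s = np.linspace(s_lo, max(s_hi, s_lo + 1e-12), n_grid)
    return best


def auroc_enumeration(scores, labels):
    """AUC by direct enumeration of all positive/negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins / (len(pos) * len(neg)))


def rank_sum_enumeration(x, y):
    """Exact two-sided rank-sum p over all C(n, nx) rank assignments."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx = len(x)
    obs = ranks[:nx].sum()
    all_sums = [
        sum(ranks[list(idx)])
        for idx in itertools.combinations(range(len(pooled)), nx)
    ]
    mean = np.mean(all_sums)
    return float(np.mean([abs(s - mean) >= abs(obs - mean) - 1e-12 for s in all_sums]))


def signed_rank_enumeration(d):
    """Exact two-sided signed-rank p over all 2^n sign patterns."""
    d = np.asarray(d, dtype=float)
    ranks = stats.rankdata(np.abs(d))
    obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(d))
    ]
    mean = np.mean(ws)
    return float(np.mean([abs(w - mean) >= abs(obs - mean) - 1e-12 for w in ws]))
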