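"""Per-study paired effect sizes and REML random-effects pooling.

The effect size is a change-score standardized mean difference: the mean
within-subject (endpoint - baseline) difference divided by the SD of those
differences, with Hedges' small-sample correction J = 1 - 3/(4(n-1)-1).
Its sampling variance uses the large-sample change-score form
``1/n + g**2/(2n)``.  Study effects are pooled under the normal-normal
random-effects model ``g_i ~ N(mu, v_i + tau2)`` with tau2 estimated by
restricted maximum likelihood and mu by inverse-variance weighting at the
REML optimum; inference on mu uses the normal (z) approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_data import CohortSet, FeatureTable, filter_min_depth, pair_samples, rarefy
from .diversity import alpha_table


@dataclass
class StudyEffect:
    study_id: str
    g: float
    var_g: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need at least 2 pairs for an effect size")
        if not self.var_g > 0:
            raise ValueError("var_g must be > 0")


@dataclass
class PooledEffect:
    mu: float
    se_mu: float
    ci95: tuple
    z: float
    p: float
    tau2: float
    Q: float
    k: int


def paired_hedges_g(baseline, endpoint, study_id: str = "") -> StudyEffect:
    """Change-score Hedges' g for paired baseline/endpoint measurements."""
    b = np.asarray(baseline, dtype=float)
    e = np.asarray(endpoint, dtype=float)
    if b.shape != e.shape:
        raise ValueError("baseline and endpoint must have equal length")
    n = b.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = e - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences: effect degenerate")
    d = diff.mean() / sd
    J = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)
    g = J * d
    var_g = 1.0 / n + g**2 / (2.0 * n)
    return StudyEffect(study_id=study_id, g=float(g), var_g=float(var_g), n=n)


def paired_ttest(baseline, endpoint):
    """Paired Student's t-test on (endpoint - baseline); two-sided.

    Returns (t, df, p).
    """
    b = np.asarray(baseline, dtype=float)
    e = np.asarray(endpoint, dtype=float)
    if b.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = e - b
    if diff.std(ddof=1) == 0:
        raise ValueError("zero variance of paired differences")
    res = stats.ttest_rel(e, b)
    return float(res.statistic), int(b.size - 1), float(res.pvalue)


def _reml_neg2ll(tau2: float, g: np.ndarray, v: np.ndarray) -> float:
    """-2 x restricted log-likelihood of the random-effects model (no const)."""
    w = 1.0 / (v + tau2)
    mu = (w * g).sum() / w.sum()
    return float(
        np.log(v + tau2).sum() + np.log(w.sum()) + (w * (g - mu) ** 2).sum()
    )


def reml_pool(effects) -> PooledEffect:
    """Pool study effects with a REML random-effects model.

    tau2 maximizes the restricted likelihood (bounded 1-D optimization with
    a coarse log-spaced pre-scan; the tau2 = 0 boundary is always a
    candidate).  mu is the inverse-variance weighted mean at the optimum.
    """
    effects = list(effects)
    k = len(effects)
    if k == 0:
        raise ValueError("no study effects to pool")
    g = np.array([e.g for e in effects])
    v = np.array([e.var_g for e in effects])
    if k == 1:
        tau2 = 0.0
    else:
        hi = max(10.0 * g.var(ddof=0), 10.0 * v.max(), 1e-3)
        grid = np.concatenate([[0.0], np.geomspace(1e-8, hi, 80)])
        vals = [_reml_neg2ll(t, g, v) for t in grid]
        i = int(np.argmin(vals))
        lo = grid[max(i - 1, 0)]
        up = grid[min(i + 1, len(grid) - 1)]
        if up > lo:
            res = optimize.minimize_scalar(
                _reml_neg2ll,
                bounds=(lo, up),
                args=(g, v),
                method="bounded",
                options={"xatol": 1e-12},
            )
            tau2 = float(res.x) if res.fun <= vals[i] else float(grid[i])
        else:
            tau2 = float(grid[i])
        if _reml_neg2ll(0.0, g, v) <= _reml_neg2ll(tau2, g, v):
            tau2 = 0.0
    w = 1.0 / (v + tau2)
    mu = float((w * g).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    z = mu / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    # Cochran's Q at fixed-effect weights (descriptive heterogeneity)
    wf = 1.0 / v
    mu_f = (wf * g).sum() / wf.sum()
    Q = float((wf * (g - mu_f) ** 2).sum())
    return PooledEffect(
        mu=mu,
        se_mu=se,
        ci95=(mu - 1.959963984540054 * se, mu + 1.959963984540054 * se),
        z=float(z),
        p=p,
        tau2=float(tau2),
        Q=Q,
        k=k,
    )


def wilcoxon_rank_sum(x, y):
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    Exact enumeration for small tie-free samples, otherwise the normal
    approximation with tie and continuity corrections.  Returns
    (U statistic of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size + y.size <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(differences):
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zeros are dropped; exact enumeration for <= 20 nonzero differences
    without ties, otherwise the normal approximation with corrections.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    has_ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 20 and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pool_alpha_diversity(
    c: CohortSet,
    metrics=("shannon", "observed_features", "faith_pd"),
    rarefaction_depth: int = 1000,
    min_depth: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-study and pooled paired effects of the intervention on alpha diversity.

    For each study: filter shallow samples, rarefy, compute alpha metrics,
    form per-subject (endpoint - baseline) effects, then REML-pool across
    studies.  Returns a long table with one row per (study, metric) and a
    ``pooled`` row per metric.
    """
    tree = c.tree
    metrics = [m for m in metrics if m != "faith_pd" or tree is not None]
    per_study_alpha = {}
    for sid, (table, meta) in c.items():
        filt = filter_min_depth(table, min_depth)
        rare = rarefy(filt, depth=rarefaction_depth, seed=seed)
        meta_kept = meta.select_samples(rare.sample_ids)
        per_study_alpha[sid] = (alpha_table(rare, tree=tree), meta_kept)

    rows = []
    for metric in metrics:
        study_effects = []
        for sid, (alpha, meta_kept) in per_study_alpha.items():
            pairs = pair_samples(meta_kept)
            if len(pairs) < 2:
                continue
            b = np.array([alpha.loc[p[0], metric] for p in pairs])
            e = np.array([alpha.loc[p[1], metric] for p in pairs])
            eff = paired_hedges_g(b, e, study_id=sid)
            _, _, p_t = paired_ttest(b, e)
            study_effects.append(eff)
            rows.append(
                {
                    "study_id": sid,
                    "metric": metric,
                    "g": eff.g,
                    "var_g": eff.var_g,
                    "n": eff.n,
                    "p": p_t,
                    "pooled": False,
                }
            )
        pooled = reml_pool(study_effects)
        rows.append(
            {
                "study_id": "Combined",
                "metric": metric,
                "g": pooled.mu,
                "var_g": pooled.se_mu**2,
                "n": sum(e.n for e in study_effects),
                "p": pooled.p,
                "pooled": True,
                "tau2": pooled.tau2,
                "ci_low": pooled.ci95[0],
                "ci_high": pooled.ci95[1],
            }
        )
    return pd.DataFrame(rows)
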