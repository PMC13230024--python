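"""Paired per-feature differential abundance via delta-CLR mixed models.

The per-feature effect measure is the within-subject CLR difference
``delta-CLR = CLR(endpoint) - CLR(baseline)`` (pseudocount 1, natural log,
CLR computed within each cohort on that cohort's post-filter feature set).
Each feature is then tested with an intercept-only random-intercept model

    delta-CLR ~ 1 + (1 | study)

fit by profiled REML, with Wald z inference and Benjamini-Hochberg FDR
across features.  The design removes subject-level baseline composition by
differencing and absorbs between-cohort shifts into the study intercept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import CohortSet, clr_transform, filter_prevalence, pair_samples
from .lmm import fit_random_intercept_lmm

logger = logging.getLogger(__name__)


@dataclass
class DeltaTable:
    """Subjects x features matrix of within-subject CLR differences."""

    values: pd.DataFrame  # index: subject_id
    study_ids: pd.Series  # subject_id -> study_id

    def __post_init__(self):
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("non-finite delta-CLR entries")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)


@dataclass
class FeatureResult:
    feature_id: str
    mu_hat: float
    se: float
    stat: float
    p: float
    q: float
    tau2: float
    sigma2: float
    per_study_means: dict


def delta_clr(
    c: CohortSet,
    prevalence: float = 0.10,
    pseudocount: float = 1.0,
    pooled_prevalence: bool = True,
) -> DeltaTable:
    """Per-subject endpoint-minus-baseline CLR differences across cohorts.

    The feature universe is the set of features passing the prevalence
    filter on the pooled samples (``pooled_prevalence=True``); CLR is then
    computed within each cohort separately on that cohort's samples, and
    differences are taken on the shared feature set.  Subjects missing a
    timepoint are excluded (count logged).
    """
    if c.mode != "paired":
        raise ValueError("delta_clr requires paired cohorts")
    pooled = pd.concat([t.counts for t, _ in c.studies.values()], axis=0)
    if pooled_prevalence:
        n = pooled.shape[0]
        need = math.ceil(prevalence * n)
        prev = (pooled > 0).sum(axis=0)
        universe = list(prev[prev >= need].index)
    else:
        universe = list(pooled.columns)
    if not universe:
        raise ValueError("no features pass the prevalence filter")

    frames, studies = [], {}
    for sid, (table, meta) in c.items():
        sub = table.select_features(universe)
        clr = clr_transform(sub, pseudocount=pseudocount)
        pairs = pair_samples(meta)
        if not pairs:
            logger.info("delta_clr: study %s has no complete pairs", sid)
            continue
        base_ids = [p[0] for p in pairs]
        end_ids = [p[1] for p in pairs]
        subj_ids = [p[2] for p in pairs]
        diff = clr.loc[end_ids].to_numpy() - clr.loc[base_ids].to_numpy()
        frames.append(pd.DataFrame(diff, index=subj_ids, columns=universe))
        studies.update({s: sid for s in subj_ids})
    if not frames:
        raise ValueError("no complete pairs in any cohort")
    values = pd.concat(frames, axis=0)
    return DeltaTable(values=values, study_ids=pd.Series(studies).loc[values.index])


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def fit_random_intercept(y, studies):
    """Intercept-only random-intercept REML fit; returns
    (mu, se_mu, tau2, sigma2, stat, p)."""
    fit = fit_random_intercept_lmm(y, studies)
    mu, se, z, p = fit.wald([1.0])
    return mu, se, fit.tau2, fit.sigma2, z, p


def run_differential_abundance(d: DeltaTable, alpha: float = 0.05) -> list:
    """Per-feature random-intercept fits with BH FDR across features.

    Returns FeatureResults sorted by (q, -|mu_hat|, feature id); the
    significant set is ``{q < alpha}``.
    """
    if d.n_subjects == 0:
        raise ValueError("empty delta table")
    studies = d.study_ids.to_numpy()
    raw = []
    for feat in d.feature_ids:
        y = d.values[feat].to_numpy()
        mu, se, tau2, sigma2, z, p = fit_random_intercept(y, studies)
        per_study = (
            pd.Series(y, index=d.values.index).groupby(d.study_ids).mean().to_dict()
        )
        raw.append((feat, mu, se, z, p, tau2, sigma2, per_study))
    pvals = np.array([r[4] for r in raw])
    finite = np.isfinite(pvals)
    qvals = np.ones_like(pvals)
    if finite.any():
        qvals[finite] = bh_fdr(pvals[finite])
    qvals[~finite] = np.nan
    results = [
        FeatureResult(
            feature_id=f,
            mu_hat=mu,
            se=se,
            stat=z,
            p=p,
            q=q,
            tau2=tau2,
            sigma2=sigma2,
            per_study_means=per_study,
        )
        for (f, mu, se, z, p, tau2, sigma2, per_study), q in zip(raw, qvals)
    ]
    results.sort(key=lambda r: (r.q if np.isfinite(r.q) else 2.0, -abs(r.mu_hat), r.feature_id))
    return results


def significant_features(results, alpha: float = 0.05) -> list:
    return [r for r in results if np.isfinite(r.q) and r.q < alpha]


def consistency_table(results, d: DeltaTable, alpha: float = 0.05) -> pd.DataFrame:
    """Per-(feature, study) mean delta-CLR for the significant features.

    A feature is flagged ``unidirectional`` when every study mean shares the
    sign of the pooled estimate.
    """
    sig = significant_features(results, alpha)
    rows = []
    for r in sig:
        uni = all(
            np.sign(m) == np.sign(r.mu_hat)
            for m in r.per_study_means.values()
            if m != 0
        )
        for sid, m in sorted(r.per_study_means.items()):
            rows.append(
                {
                    "feature_id": r.feature_id,
                    "study_id": sid,
                    "mean_delta_clr": m,
                    "mu_hat": r.mu_hat,
                    "q": r.q,
                    "unidirectional": uni,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["feature_id", "study_id", "mean_delta_clr", "mu_hat", "q", "unidirectional"],
    )


def results_frame(results) -> pd.DataFrame:
    """FeatureResults as a tidy frame (one row per feature)."""
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "mu_hat": r.mu_hat,
                "se": r.se,
                "stat": r.stat,
                "p": r.p,
                "q": r.q,
                "tau2": r.tau2,
                "sigma2": r.sigma2,
            }
            for r in results
        ]
    )
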