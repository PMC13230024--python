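"""Cross-sectional disease validation of an intervention-depleted module.

Given a fixed module of feature ids (the set depleted by the intervention
in the paired analysis), each cross-sectional sample is scored by the sum
of the module features' relative abundances.  Diagnosis effects on the
score are estimated with a mixed model

    module_score ~ diagnosis + (1 | study)

fit by profiled REML (the same engine as the paired differential-abundance
stage, generalized to a fixed-effects design).  Marginal means are the
model-predicted group means at a zero random effect; all pairwise contrasts
are Wald z-tests with BH FDR.  A LOSO random-forest comparison contrasts
the discriminative value of the full feature table against the module
alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import CohortSet, FeatureTable, SampleMetadata, relative_abundance
from .diffab import bh_fdr
from .lmm import fit_random_intercept_lmm
from .meta_effects import wilcoxon_signed_rank
from . import mlval

logger = logging.getLogger(__name__)


@dataclass
class ModuleDefinition:
    feature_ids: list

    def __post_init__(self):
        if not self.feature_ids:
            raise ValueError("module must be nonempty")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids in module")

    @classmethod
    def read(cls, path) -> "ModuleDefinition":
        with open(path) as fh:
            ids = [ln.strip() for ln in fh if ln.strip()]
        return cls(ids)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.feature_ids) + "\n")


@dataclass
class DiagnosisLmmResult:
    marginal_means: pd.Series  # diagnosis -> adjusted mean on the score scale
    contrasts: pd.DataFrame  # pair, estimate, se, stat, p, q
    tau2: float
    sigma2: float


def module_score(rel_abund: pd.DataFrame, module: ModuleDefinition) -> pd.Series:
    """Per-sample sum of the module features' relative abundances (in [0, 1]).

    Module members absent from the table contribute 0 (logged), since
    feature sets can differ across cohorts.
    """
    present = [f for f in module.feature_ids if f in rel_abund.columns]
    missing = len(module.feature_ids) - len(present)
    if missing:
        logger.warning("module_score: %d module feature(s) absent, scored as 0", missing)
    if not present:
        return pd.Series(0.0, index=rel_abund.index)
    return rel_abund[present].sum(axis=1)


def cohens_d(a, b) -> float:
    """Cohen's d with the pooled-SD denominator."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise ValueError("zero pooled SD")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def fit_diagnosis_lmm(scores, diagnoses, studies) -> DiagnosisLmmResult:
    """Diagnosis fixed effects + study random intercept on module scores.

    Reference-coded design (first diagnosis level alphabetically is the
    reference); marginal means are invariant to that choice.  Contrast
    p-values are BH-adjusted across all pairwise comparisons.
    """
    scores = np.asarray(scores, dtype=float)
    diagnoses = np.asarray(diagnoses)
    studies = np.asarray(studies)
    levels = sorted(set(diagnoses))
    if len(levels) < 2:
        raise ValueError("need >= 2 diagnosis levels")
    # drop levels present in zero studies (vacuous here, but symmetrical
    # with the contract that a diagnosis can be absent from some cohorts)
    X = np.ones((scores.size, len(levels)))
    for j, lev in enumerate(levels[1:], start=1):
        X[:, j] = (diagnoses == lev).astype(float)
    fit = fit_random_intercept_lmm(scores, studies, X)
    means = {levels[0]: fit.beta[0]}
    for j, lev in enumerate(levels[1:], start=1):
        means[lev] = fit.beta[0] + fit.beta[j]
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            c = np.zeros(len(levels))
            if i > 0:
                c[i] = 1.0
            if j > 0:
                c[j] -= 1.0
            est, se, z, p = fit.wald(c)
            rows.append(
                {
                    "pair": f"{levels[i]}-{levels[j]}",
                    "estimate": est,
                    "se": se,
                    "stat": z,
                    "p": p,
                }
            )
    contrasts = pd.DataFrame(rows)
    contrasts["q"] = bh_fdr(contrasts["p"].to_numpy())
    return DiagnosisLmmResult(
        marginal_means=pd.Series(means),
        contrasts=contrasts,
        tau2=fit.tau2,
        sigma2=fit.sigma2,
    )


def module_analysis(c: CohortSet, module: ModuleDefinition) -> DiagnosisLmmResult:
    """Score every sample of a cross-sectional cohort set and fit the LMM."""
    scores, diags, studs = [], [], []
    for sid, (table, meta) in c.items():
        s = module_score(relative_abundance(table), module)
        cond = meta.condition_of()
        for samp in s.index:
            scores.append(s[samp])
            diags.append(cond[samp])
            studs.append(sid)
    return fit_diagnosis_lmm(np.array(scores), np.array(diags), np.array(studs))


def _contrast_subset(c: CohortSet, groups) -> CohortSet:
    """Restrict to studies having both groups; relabel for binary mlval."""
    keep = {}
    excluded = []
    for sid, (table, meta) in c.items():
        cond = meta.condition_of()
        if all((cond == g).any() for g in groups):
            ids = cond[cond.isin(groups)].index
            keep[sid] = (table.select_samples(ids), meta.select_samples(ids))
        else:
            excluded.append(sid)
    if excluded:
        logger.info(
            "contrast %s: excluded %d cohort(s) lacking a group: %s",
            "/".join(groups),
            len(excluded),
            excluded,
        )
    return CohortSet(keep, tree=c.tree)


def loso_disease_classifier(
    c: CohortSet,
    module: ModuleDefinition,
    contrast: str = "HC_vs_CD",
    seed: int = 0,
) -> pd.DataFrame:
    """LOSO random-forest AUCs for a disease contrast, full table vs module.

    Cohorts lacking either contrast group are excluded.  Returns one row
    per (cohort, feature set); the per-cohort AUC differences between the
    full and module feature sets are compared with a paired Wilcoxon
    signed-rank test, reported in the frame attributes.
    """
    groups = {"HC_vs_CD": ("HC", "CD"), "HC_vs_UC": ("HC", "UC")}[contrast]
    sub = _contrast_subset(c, groups)
    if len(sub.study_ids) < 2:
        raise ValueError("need >= 2 cohorts with both contrast groups")
    positive = groups[1]  # disease class is the positive label
    rows = []
    aucs = {}
    for feature_set in ("full", "module"):
        # module subset applied after normalization: features keep their
        # whole-community relative-abundance scale
        subset = module.feature_ids if feature_set == "module" else None
        res = mlval.loso(
            sub,
            feature_kind="relative",
            seed=seed,
            positive=positive,
            feature_subset=subset,
        )
        for r in res:
            aucs.setdefault(r.test_scope, {})[feature_set] = r.auc
            rows.append(
                {
                    "cohort": r.test_scope,
                    "feature_set": feature_set,
                    "contrast": contrast,
                    "auc": r.auc,
                    "n_test": r.n_test,
                }
            )
    out = pd.DataFrame(rows)
    diffs = [v["full"] - v["module"] for v in aucs.values()]
    try:
        _, p = wilcoxon_signed_rank(diffs)
    except ValueError:  # identical AUCs in every cohort
        p = 1.0
    out.attrs["signed_rank_p"] = p
    out.attrs["mean_auc_full"] = float(np.mean([v["full"] for v in aucs.values()]))
    out.attrs["mean_auc_module"] = float(np.mean([v["module"] for v in aucs.values()]))
    return out
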