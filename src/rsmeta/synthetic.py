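"""Synthetic multi-cohort microbiome data with planted ground truth.

The generator emulates the statistical structure of a multi-study paired
dietary-intervention design: several studies with distinct baseline
compositions (study-level random effects), strong subject-level pairing
(subject effects shared by both of a subject's samples), an intervention
that depletes a designated feature module on the log scale, variable
sequencing depth, and multinomial count noise.  A cross-sectional variant
emulates case/control disease cohorts with diagnosis-dependent enrichment
of the same module.

The model is logistic-normal/multinomial: latent per-sample log-weights

    eta_k = beta_k + u_(study,k) + s_(subject,k) + t * delta_k + eps

are passed through a softmax and counts are drawn
``Multinomial(depth, softmax(eta))`` with depth uniform on a configured
range.  Because the CLR of the softmax weights is ``eta`` minus its mean,
the within-subject CLR difference inherits exactly the additive structure
assumed by the downstream random-intercept model — so parameter recovery is
a meaningful end-to-end check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core_data import CohortSet, FeatureTable, SampleMetadata

__all__ = [
    "PairedSimConfig",
    "CrossSectionalSimConfig",
    "GroundTruth",
    "simulate_tree",
    "simulate_paired_cohorts",
    "simulate_ibd_cohorts",
    "default_recovery_config",
]


@dataclass
class PairedSimConfig:
    """Configuration for the paired-intervention generator.

    Defaults mirror the geometry of the real design this package targets:
    7 studies of 30 subjects, 200 features of which a 22-feature module is
    depleted by ``delta = -0.8`` on the log scale, with realistic study
    (0.5), subject (1.0) and residual (0.5) log-scale SDs and sequencing
    depths between 5,000 and 20,000 reads.
    """

    n_studies: int = 7
    subjects_per_study: list = None
    n_features: int = 200
    n_module: int = 22
    delta: float = -0.8
    sigma_study: float = 0.5
    sigma_subject: float = 1.0
    sigma_noise: float = 0.5
    depth_range: tuple = (5000, 20000)
    seed: int = 0

    def __post_init__(self):
        if self.subjects_per_study is None:
            self.subjects_per_study = [30] * self.n_studies
        if len(self.subjects_per_study) != self.n_studies:
            raise ValueError("subjects_per_study length must equal n_studies")
        if not 0 <= self.n_module <= self.n_features:
            raise ValueError("n_module must be in [0, n_features]")
        for name in ("sigma_study", "sigma_subject", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.depth_range[0] < 1 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("invalid depth_range")


@dataclass
class CrossSectionalSimConfig:
    """Configuration for the cross-sectional disease-cohort generator.

    ``group_sizes`` maps each study index to ``{"HC": n, "CD": n, "UC": n}``;
    a size of 0 omits that diagnosis from that study.  ``diagnosis_shift``
    is the per-diagnosis log-scale enrichment applied to module features
    (HC conventionally 0).
    """

    n_studies: int = 4
    group_sizes: list = None  # list of {"HC": int, "CD": int, "UC": int}
    n_features: int = 200
    n_module: int = 22
    diagnosis_shift: dict = field(
        default_factory=lambda: {"HC": 0.0, "CD": 1.0, "UC": 0.4}
    )
    sigma_study: float = 0.5
    sigma_noise: float = 1.0
    depth_range: tuple = (5000, 20000)
    seed: int = 0

    def __post_init__(self):
        if self.group_sizes is None:
            self.group_sizes = [{"HC": 40, "CD": 40, "UC": 40}] * self.n_studies
        if len(self.group_sizes) != self.n_studies:
            raise ValueError("group_sizes length must equal n_studies")
        for sizes in self.group_sizes:
            if any(v < 0 for v in sizes.values()):
                raise ValueError("group sizes must be >= 0")
        for v in self.diagnosis_shift.values():
            if not np.isfinite(v):
                raise ValueError("diagnosis shifts must be finite")


@dataclass
class GroundTruth:
    """Planted truth recorded alongside a simulated cohort set."""

    module_features: list
    delta: pd.Series  # per-feature true intervention / enrichment effect
    study_offsets: pd.DataFrame  # study x feature realized random offsets


def default_recovery_config(seed: int = 0) -> PairedSimConfig:
    """The default planted-effect recovery scenario."""
    return PairedSimConfig(seed=seed)


def simulate_tree(n_features: int, seed: int, prefix: str = "F") -> TreeNode:
    """Random rooted bifurcating tree over features ``F0001..``.

    Built by repeated random joins of subtrees; branch lengths are i.i.d.
    exponential with mean 0.1.  Deterministic for a given seed.
    """
    if n_features < 2:
        raise ValueError("need at least 2 features to build a tree")
    rng = np.random.default_rng(seed)
    names = feature_names(n_features, prefix)
    nodes = [TreeNode(name=nm, length=float(rng.exponential(0.1))) for nm in names]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(0.1)), children=[left, right])
        nodes.append(parent)
    return TreeNode(length=0.0, children=nodes)


def feature_names(n: int, prefix: str = "F") -> list:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _draw_depths(rng, n, depth_range):
    return rng.integers(depth_range[0], depth_range[1] + 1, size=n)


def _softmax_counts(rng, eta, depth):
    w = np.exp(eta - eta.max())
    return rng.multinomial(int(depth), w / w.sum())


def simulate_paired_cohorts(cfg: PairedSimConfig):
    """Simulate paired baseline/endpoint cohorts.

    Returns
    -------
    (CohortSet, GroundTruth)
        One study per entry of ``cfg.subjects_per_study``; each subject has
        exactly one baseline and one endpoint sample.  The first
        ``cfg.n_module`` features form the planted depleted module with
        log-scale effect ``cfg.delta``; all other features have effect 0.
    """
    rng = np.random.default_rng(cfg.seed)
    feats = feature_names(cfg.n_features)
    module = feats[: cfg.n_module]
    delta = np.zeros(cfg.n_features)
    delta[: cfg.n_module] = cfg.delta
    beta = rng.normal(0.0, 1.0, size=cfg.n_features)

    studies = {}
    offsets = {}
    for i, n_subj in enumerate(cfg.subjects_per_study):
        study_id = f"S{i + 1:02d}"
        u = rng.normal(0.0, cfg.sigma_study, size=cfg.n_features)
        offsets[study_id] = u
        depths = _draw_depths(rng, 2 * n_subj, cfg.depth_range)
        counts, meta_rows = [], []
        sample_ids = []
        for j in range(n_subj):
            subject = f"{study_id}_subj{j + 1:03d}"
            s = rng.normal(0.0, cfg.sigma_subject, size=cfg.n_features)
            for t, tp in enumerate(("baseline", "endpoint")):
                eps = rng.normal(0.0, cfg.sigma_noise, size=cfg.n_features)
                eta = beta + u + s + t * delta + eps
                sample = f"{subject}_{tp}"
                counts.append(_softmax_counts(rng, eta, depths[2 * j + t]))
                sample_ids.append(sample)
                meta_rows.append(
                    {
                        "sample_id": sample,
                        "study_id": study_id,
                        "subject_id": subject,
                        "timepoint": tp,
                    }
                )
        table = FeatureTable(
            pd.DataFrame(np.array(counts), index=sample_ids, columns=feats)
        )
        meta = SampleMetadata(pd.DataFrame(meta_rows), "paired")
        studies[study_id] = (table, meta)

    truth = GroundTruth(
        module_features=module,
        delta=pd.Series(delta, index=feats),
        study_offsets=pd.DataFrame(offsets, index=feats).T,
    )
    return CohortSet(studies), truth


def simulate_ibd_cohorts(cfg: CrossSectionalSimConfig):
    """Simulate cross-sectional HC/CD/UC cohorts with module enrichment.

    Study offsets are shared by all diagnosis groups within a study;
    ``diagnosis_shift`` is added to module features only.
    """
    rng = np.random.default_rng(cfg.seed)
    feats = feature_names(cfg.n_features)
    module = feats[: cfg.n_module]
    is_module = np.zeros(cfg.n_features)
    is_module[: cfg.n_module] = 1.0
    beta = rng.normal(0.0, 1.0, size=cfg.n_features)

    studies = {}
    offsets = {}
    for i, sizes in enumerate(cfg.group_sizes):
        study_id = f"I{i + 1:02d}"
        u = rng.normal(0.0, cfg.sigma_study, size=cfg.n_features)
        offsets[study_id] = u
        counts, meta_rows, sample_ids = [], [], []
        k = 0
        for diag in ("HC", "CD", "UC"):
            shift = cfg.diagnosis_shift.get(diag, 0.0)
            for _ in range(sizes.get(diag, 0)):
                k += 1
                eps = rng.normal(0.0, cfg.sigma_noise, size=cfg.n_features)
                eta = beta + u + shift * is_module + eps
                depth = _draw_depths(rng, 1, cfg.depth_range)[0]
                sample = f"{study_id}_samp{k:04d}"
                counts.append(_softmax_counts(rng, eta, depth))
                sample_ids.append(sample)
                meta_rows.append(
                    {
                        "sample_id": sample,
                        "study_id": study_id,
                        "subject_id": sample,  # one sample per subject
                        "diagnosis": diag,
                    }
                )
        table = FeatureTable(
            pd.DataFrame(np.array(counts), index=sample_ids, columns=feats)
        )
        meta = SampleMetadata(pd.DataFrame(meta_rows), "cross_sectional")
        studies[study_id] = (table, meta)

    shifts = pd.Series(
        {d: cfg.diagnosis_shift.get(d, 0.0) for d in ("HC", "CD", "UC")}
    )
    truth = GroundTruth(
        module_features=module,
        delta=pd.Series(is_module * shifts["CD"], index=feats),
        study_offsets=pd.DataFrame(offsets, index=feats).T,
    )
    truth.diagnosis_shift = shifts
    return CohortSet(studies), truth
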