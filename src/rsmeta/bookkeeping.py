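"""Published cohort rosters and builders for bookkeeping checks.

The analysis targets two collections of public 16S amplicon datasets: seven
paired resistant-starch intervention cohorts (293 subjects, 586 paired
samples in total) and eight cross-sectional IBD cohorts (2,491 samples
across healthy controls, Crohn's disease and ulcerative colitis).  Raw
sequence data are never downloaded here; the rosters below carry only the
per-cohort sample bookkeeping, and the builders materialize metadata-level
cohort sets against which :func:`rsmeta.core_data.cohort_summary` can be
checked exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_data import CohortSet, FeatureTable, SampleMetadata

# Paired RS intervention cohorts: accession -> (n subjects, RS class)
INTERVENTION_COHORTS = {
    "PRJEB41443": (30, "RS2"),
    "PRJNA293971": (20, "RS1"),
    "PRJNA306884": (20, "RS2"),
    "PRJNA891951": (57, "RS4"),
    "PRJNA428736": (86, "RS2"),
    "PRJNA560950": (30, "RS4"),
    "PRJNA780023": (50, "RS2"),
}

RS_CLASS_MAP = {acc: cls for acc, (_, cls) in INTERVENTION_COHORTS.items()}

# Cross-sectional IBD cohorts: accession -> {HC, CD, UC} sample counts
# (0 = diagnosis not available in that cohort)
IBD_COHORTS = {
    "PRJNA324147": {"HC": 53, "CD": 25, "UC": 10},
    "PRJNA368966": {"HC": 29, "CD": 0, "UC": 32},
    "PRJNA422193": {"HC": 34, "CD": 34, "UC": 39},
    "PRJNA431126": {"HC": 34, "CD": 185, "UC": 97},
    "PRJNA450340": {"HC": 45, "CD": 42, "UC": 39},
    "RISK_PRISM_f": {"HC": 65, "CD": 362, "UC": 105},
    "qiita_1629": {"HC": 55, "CD": 211, "UC": 286},
    "qiita_2538": {"HC": 360, "CD": 349, "UC": 0},
}


def _placeholder_table(sample_ids) -> FeatureTable:
    # single-feature count table; bookkeeping uses metadata only
    df = pd.DataFrame(
        np.ones((len(sample_ids), 1), dtype=int), index=sample_ids, columns=["F0001"]
    )
    return FeatureTable(df)


def intervention_roster_cohorts() -> CohortSet:
    """Metadata-level paired cohort set matching the intervention roster."""
    studies = {}
    for acc, (n_subj, _) in INTERVENTION_COHORTS.items():
        rows = []
        for j in range(1, n_subj + 1):
            subject = f"{acc}_subj{j:03d}"
            for tp in ("baseline", "endpoint"):
                rows.append(
                    {
                        "sample_id": f"{subject}_{tp}",
                        "study_id": acc,
                        "subject_id": subject,
                        "timepoint": tp,
                    }
                )
        meta = SampleMetadata(pd.DataFrame(rows), "paired")
        studies[acc] = (_placeholder_table(meta.sample_ids), meta)
    return CohortSet(studies)


def ibd_roster_cohorts() -> CohortSet:
    """Metadata-level cross-sectional cohort set matching the IBD roster."""
    studies = {}
    for acc, sizes in IBD_COHORTS.items():
        rows = []
        k = 0
        for diag in ("HC", "CD", "UC"):
            for _ in range(sizes[diag]):
                k += 1
                sample = f"{acc}_samp{k:04d}"
                rows.append(
                    {
                        "sample_id": sample,
                        "study_id": acc,
                        "subject_id": sample,
                        "diagnosis": diag,
                    }
                )
        meta = SampleMetadata(pd.DataFrame(rows), "cross_sectional")
        studies[acc] = (_placeholder_table(meta.sample_ids), meta)
    return CohortSet(studies)
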