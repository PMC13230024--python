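import numpy as np
import pandas as pd
import pytest

from rsmeta.core_data import CohortSet, FeatureTable, SampleMetadata
from rsmeta.synthetic import PairedSimConfig, simulate_paired_cohorts, simulate_tree


@pytest.fixture
def tiny_table():
    return FeatureTable(
        pd.DataFrame(
            [[5, 0, 3], [1, 3, 4], [2, 2, 4]],
            index=["s1", "s2", "s3"],
            columns=["fA", "fB", "fC"],
        )
    )


@pytest.fixture
def paired_meta():
    rows = []
    for subj in ("p1", "p2", "p3"):
        for tp in ("baseline", "endpoint"):
            rows.append(
                {
                    "sample_id": f"{subj}_{tp}",
                    "study_id": "S01",
                    "subject_id": subj,
                    "timepoint": tp,
                }
            )
    return SampleMetadata(pd.DataFrame(rows), "paired")


@pytest.fixture(scope="session")
def small_cohorts():
    """2 studies x 12 subjects, 40 features, planted 6-feature module."""
    cfg = PairedSimConfig(
        n_studies=2,
        subjects_per_study=[12, 12],
        n_features=40,
        n_module=6,
        delta=-1.0,
        depth_range=(2000, 4000),
        seed=7,
    )
    cohorts, truth = simulate_paired_cohorts(cfg)
    cohorts.tree = simulate_tree(cfg.n_features, seed=8)
    return cohorts, truth
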