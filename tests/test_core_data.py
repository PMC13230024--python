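import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from rsmeta.core_data import (
    CohortSet,
    FeatureTable,
    FormatError,
    SampleMetadata,
    ValidationError,
    clr_transform,
    cohort_summary,
    filter_min_depth,
    filter_prevalence,
    pair_samples,
    rarefy,
    read_feature_table,
    read_metadata,
    read_tree,
    relative_abundance,
    write_feature_table,
    write_metadata,
    write_tree,
)

count_matrices = arrays(
    np.int64, (4, 6), elements=st.integers(min_value=0, max_value=500)
)


# --- I/O and validation -----------------------------------------------------

def test_feature_table_roundtrip(tmp_path, tiny_table):
    path = tmp_path / "t.tsv"
    write_feature_table(tiny_table, path)
    back = read_feature_table(path)
    assert back == tiny_table
    assert back.sample_ids == tiny_table.sample_ids
    assert back.feature_ids == tiny_table.feature_ids


@pytest.mark.parametrize(
    "bad",
    [
        [[5, -1], [1, 3]],  # negative
        [[5, 0.5], [1, 3]],  # non-integral
    ],
)
def test_feature_table_rejects_invalid_entries(bad):
    with pytest.raises(FormatError):
        FeatureTable(pd.DataFrame(bad, index=["a", "b"], columns=["x", "y"]))


def test_feature_table_rejects_duplicate_ids():
    with pytest.raises(FormatError):
        FeatureTable(pd.DataFrame([[1], [2]], index=["a", "a"], columns=["x"]))


def test_metadata_roundtrip_and_pairs(tmp_path, paired_meta):
    path = tmp_path / "m.tsv"
    write_metadata(paired_meta, path)
    back = read_metadata(path, "paired")
    assert back.table.equals(paired_meta.table)
    assert len(pair_samples(back)) == 3


def test_metadata_rejects_duplicate_subject_timepoint():
    rows = pd.DataFrame(
        {
            "sample_id": ["a", "b"],
            "study_id": ["S", "S"],
            "subject_id": ["p1", "p1"],
            "timepoint": ["baseline", "baseline"],
        }
    )
    with pytest.raises(ValidationError):
        SampleMetadata(rows, "paired")


def test_metadata_rejects_unknown_diagnosis():
    rows = pd.DataFrame(
        {
            "sample_id": ["a"],
            "study_id": ["S"],
            "subject_id": ["p"],
            "diagnosis": ["ibd"],
        }
    )
    with pytest.raises(ValidationError):
        SampleMetadata(rows, "cross_sectional")
    rows["diagnosis"] = ["UC"]
    assert SampleMetadata(rows, "cross_sectional").table["diagnosis"].iloc[0] == "UC"


def test_read_tree_examples(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((A:1,B:1):1,C:2):0;\n")
    tree = read_tree(p)
    tips = sorted(lf.name for lf in tree.tips())
    assert tips == ["A", "B", "C"]
    total = sum(n.length for n in tree.traverse(include_self=False))
    assert total == pytest.approx(5.0)

    p.write_text("((A,B),C);\n")
    with pytest.raises(ValidationError):
        read_tree(p)

    p.write_text("(A:1,B:1,C:2):0;\n")  # trifurcating root
    with pytest.raises(ValidationError, match="root"):
        read_tree(p)


def test_tree_roundtrip(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((A:1.5,B:1):1,C:2):0;\n")
    tree = read_tree(p)
    q = tmp_path / "back.nwk"
    write_tree(tree, q)
    back = read_tree(q)
    assert {lf.name: lf.length for lf in back.tips()} == {
        lf.name: lf.length for lf in tree.tips()
    }


# --- filtering --------------------------------------------------------------

def test_filter_min_depth_threshold():
    t = FeatureTable(
        pd.DataFrame(
            [[999, 0], [1000, 0], [2000, 500]],
            index=["a", "b", "c"],
            columns=["x", "y"],
        )
    )
    kept = filter_min_depth(t, 1000)
    assert kept.sample_ids == ["b", "c"]
    assert filter_min_depth(t, 0) == t
    # idempotence
    assert filter_min_depth(kept, 1000) == kept
    with pytest.warns(UserWarning):
        empty = filter_min_depth(t, 10**6)
    assert empty.shape[0] == 0


def test_filter_prevalence_boundaries():
    # 1 of 20 samples at 10% needs ceil(2.0)=2 -> dropped
    counts = np.zeros((20, 2), dtype=int)
    counts[:, 0] = 5
    counts[0, 1] = 5
    t = FeatureTable(pd.DataFrame(counts, columns=["common", "rare"]))
    assert filter_prevalence(t, 0.10).feature_ids == ["common"]
    assert filter_prevalence(t, 0.0) == t
    # 10 samples, present in exactly 1: ceil(1.0)=1 -> kept
    t10 = FeatureTable(pd.DataFrame(counts[:10], columns=["common", "rare"]))
    assert filter_prevalence(t10, 0.10).feature_ids == ["common", "rare"]


# --- rarefaction ------------------------------------------------------------

def test_rarefy_contracts():
    t = FeatureTable(pd.DataFrame([[10, 0], [600, 600]], columns=["x", "y"]))
    out = rarefy(t, depth=10, seed=1)
    assert out.counts.iloc[0].tolist() == [10, 0]  # whole-sample subsample
    assert (out.counts.sum(axis=1) == 10).all()
    assert rarefy(t, depth=10, seed=1) == out  # bit-for-bit reproducible
    with pytest.raises(ValueError, match="filter_min_depth"):
        rarefy(t, depth=100, seed=1)


def test_rarefy_hypergeometric_expectation():
    """Mean of the first entry over many seeds matches the hypergeometric
    expectation depth * K/N within 3 standard errors."""
    t = FeatureTable(pd.DataFrame([[500, 500]], columns=["x", "y"]))
    depth, reps = 100, 2000
    draws = np.array(
        [rarefy(t, depth=depth, seed=s).counts.iloc[0, 0] for s in range(reps)]
    )
    # hypergeometric(N=1000, K=500, n=100): mean 50, var n*K/N*(1-K/N)*(N-n)/(N-1)
    var = depth * 0.5 * 0.5 * (1000 - depth) / 999
    se = np.sqrt(var / reps)
    assert abs(draws.mean() - 50.0) < 3 * se


# --- pairing ----------------------------------------------------------------

def test_pair_samples_drops_incomplete():
    rows = []
    for subj, tps in [("p1", ["baseline", "endpoint"]), ("p2", ["baseline", "endpoint"]), ("p3", ["baseline"])]:
        for tp in tps:
            rows.append(
                {
                    "sample_id": f"{subj}_{tp}",
                    "study_id": "S",
                    "subject_id": subj,
                    "timepoint": tp,
                }
            )
    m = SampleMetadata(pd.DataFrame(rows), "paired")
    pairs = pair_samples(m)
    assert len(pairs) == 2
    assert all(b.endswith("baseline") and e.endswith("endpoint") for b, e, *_ in pairs)


def test_pair_samples_empty():
    m = SampleMetadata(
        pd.DataFrame(columns=["sample_id", "study_id", "subject_id", "timepoint"]),
        "paired",
    )
    assert pair_samples(m) == []


def test_pair_samples_within_study_only():
    # same subject id with baseline in one study and endpoint in another:
    # no cross-study pair is formed
    rows = [
        {"sample_id": "a", "study_id": "S1", "subject_id": "p", "timepoint": "baseline"},
        {"sample_id": "b", "study_id": "S2", "subject_id": "p", "timepoint": "endpoint"},
        {"sample_id": "c", "study_id": "S2", "subject_id": "q", "timepoint": "baseline"},
        {"sample_id": "d", "study_id": "S2", "subject_id": "q", "timepoint": "endpoint"},
    ]
    pairs = pair_samples(SampleMetadata(pd.DataFrame(rows), "paired"))
    assert [(p[2], p[3]) for p in pairs] == [("q", "S2")]


@given(count_matrices)
@settings(max_examples=30, deadline=None)
def test_pair_count_matches_brute_force(counts):
    # random assignment of 4 subjects to timepoints via the matrix parity
    rng = np.random.default_rng(int(abs(counts).sum()) % 2**31)
    rows = []
    k = 0
    for subj in range(6):
        for tp in ("baseline", "endpoint"):
            if rng.random() < 0.7:
                rows.append(
                    {
                        "sample_id": f"s{k}",
                        "study_id": "S",
                        "subject_id": f"p{subj}",
                        "timepoint": tp,
                    }
                )
                k += 1
    if not rows:
        return
    df = pd.DataFrame(rows)
    m = SampleMetadata(df, "paired")
    expected = sum(
        1
        for _, grp in df.groupby("subject_id")
        if set(grp["timepoint"]) == {"baseline", "endpoint"}
    )
    assert len(pair_samples(m)) == expected


# --- transforms -------------------------------------------------------------

def test_relative_abundance_examples():
    t = FeatureTable(pd.DataFrame([[2, 2, 4]], columns=["a", "b", "c"]))
    assert relative_abundance(t).iloc[0].tolist() == [0.25, 0.25, 0.5]
    one = FeatureTable(pd.DataFrame([[7], [3]], columns=["a"]))
    assert (relative_abundance(one) == 1.0).all().all()
    zero = FeatureTable(pd.DataFrame([[0, 0]], columns=["a", "b"]))
    with pytest.raises(ValueError):
        relative_abundance(zero)


def test_clr_examples():
    t = FeatureTable(pd.DataFrame([[1, 1, 1]], columns=list("abc")))
    assert np.allclose(clr_transform(t), 0.0)
    t2 = FeatureTable(pd.DataFrame([[9, 0]], columns=["a", "b"]))
    v = clr_transform(t2, pseudocount=1).iloc[0]
    assert v["a"] == pytest.approx(np.log(10) / 2, abs=1e-5)
    assert v["b"] == pytest.approx(-np.log(10) / 2, abs=1e-5)


@given(count_matrices)
@settings(max_examples=50, deadline=None)
def test_transform_row_sum_invariants(counts):
    t = FeatureTable(pd.DataFrame(counts))
    clr = clr_transform(t)
    assert np.all(np.abs(clr.sum(axis=1)) < 1e-9)
    if (counts.sum(axis=1) > 0).all():
        rel = relative_abundance(t)
        assert np.all(np.abs(rel.sum(axis=1) - 1) < 1e-12)


# --- bookkeeping ------------------------------------------------------------

def test_cohort_summary_empty():
    s = cohort_summary(CohortSet({}))
    assert s.iloc[-1]["n_subjects"] == 0


def test_cohort_summary_totals(small_cohorts):
    cohorts, _ = small_cohorts
    s = cohort_summary(cohorts)
    total = s[s["study_id"] == "Total"].iloc[0]
    per_study = s[s["study_id"] != "Total"]
    assert total["n_subjects"] == per_study["n_subjects"].sum() == 24
    assert total["n_paired_samples"] == 48
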