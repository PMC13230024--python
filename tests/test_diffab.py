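import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rsmeta.core_data import CohortSet, FeatureTable, SampleMetadata
from rsmeta.diffab import (
    DeltaTable,
    bh_fdr,
    consistency_table,
    delta_clr,
    fit_random_intercept,
    results_frame,
    run_differential_abundance,
    significant_features,
)
from rsmeta.lmm import fit_random_intercept_lmm


def _one_subject_cohort(base_counts, end_counts):
    feats = [f"f{i}" for i in range(len(base_counts))]
    counts = pd.DataFrame(
        [base_counts, end_counts], index=["p1_b", "p1_e"], columns=feats
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ["p1_b", "p1_e"],
                "study_id": ["S", "S"],
                "subject_id": ["p1", "p1"],
                "timepoint": ["baseline", "endpoint"],
            }
        ),
        "paired",
    )
    return CohortSet({"S": (FeatureTable(counts), meta)})


# --- delta-CLR --------------------------------------------------------------

def test_delta_clr_identical_counts_zero():
    c = _one_subject_cohort([10, 20, 30], [10, 20, 30])
    d = delta_clr(c, prevalence=0.0)
    assert np.allclose(d.values.to_numpy(), 0.0)


def test_delta_clr_doubling_one_feature():
    """Doubling one feature's count gives it a positive delta and small
    negative deltas elsewhere (centering)."""
    c = _one_subject_cohort([1000, 1000, 1000], [2000, 1000, 1000])
    d = delta_clr(c, prevalence=0.0).values.iloc[0]
    assert d["f0"] > 0
    assert d["f1"] < 0 and d["f2"] < 0
    # hand computation: delta_f0 = ln(2001/1001) * 2/3
    expected = np.log(2001 / 1001) - (np.log(2001 / 1001)) / 3
    assert d["f0"] == pytest.approx(expected, abs=1e-9)


def test_delta_clr_row_count_and_studies(small_cohorts):
    cohorts, _ = small_cohorts
    d = delta_clr(cohorts)
    assert d.n_subjects == 24
    assert set(d.study_ids) == {"S01", "S02"}


# --- BH FDR -----------------------------------------------------------------

def test_bh_fdr_examples():
    assert bh_fdr([0.04])[0] == pytest.approx(0.04)
    q = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


def test_bh_fdr_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(0)
    p = rng.uniform(size=50)
    q = bh_fdr(p)
    _, q_sm, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(q, q_sm)


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
@settings(max_examples=50, deadline=None)
def test_bh_fdr_properties(p):
    p = np.array(p)
    q = bh_fdr(p)
    assert np.all(q >= p - 1e-15)
    assert np.all(q <= 1.0)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-12)  # monotone in p


# --- random-intercept REML fit ---------------------------------------------

def test_fit_single_study_collapses_to_one_sample_z():
    rng = np.random.default_rng(1)
    y = rng.normal(0.5, 1.0, 40)
    mu, se, tau2, sigma2, z, p = fit_random_intercept(y, np.repeat("S1", 40))
    assert mu == pytest.approx(y.mean())
    assert tau2 == pytest.approx(0.0, abs=1e-8)
    # REML sigma2 with a single group equals the sample variance (ddof=1)
    assert sigma2 == pytest.approx(y.var(ddof=1), rel=1e-6)
    assert se == pytest.approx(np.sqrt(y.var(ddof=1) / 40), rel=1e-6)


def test_fit_balanced_two_studies_matches_anova_moments():
    """Study means +1/-1 with tiny noise: mu ~ 0, tau2 ~ 1 (within 10% of the
    one-way random-effects method-of-moments estimate)."""
    rng = np.random.default_rng(2)
    n = 200
    y = np.concatenate([rng.normal(1.0, 0.05, n), rng.normal(-1.0, 0.05, n)])
    studies = np.repeat(["A", "B"], n)
    mu, se, tau2, sigma2, z, p = fit_random_intercept(y, studies)
    assert abs(mu) < 0.2
    gm = [y[:n].mean(), y[n:].mean()]
    msb = n * np.var(gm, ddof=1)
    msw = (y[:n].var(ddof=1) + y[n:].var(ddof=1)) / 2
    tau2_mom = (msb - msw) / n
    assert tau2 == pytest.approx(tau2_mom, rel=0.10)


def test_fit_matches_statsmodels_mixedlm():
    rng = np.random.default_rng(3)
    ns = [8, 15, 12, 20]
    y = np.concatenate(
        [rng.normal(rng.normal(0, 0.8), 1.0, n) for n in ns]
    )
    studies = np.concatenate([[f"S{i}"] * n for i, n in enumerate(ns)])
    mu, se, tau2, sigma2, _, _ = fit_random_intercept(y, studies)
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": y, "g": studies})
    m = smf.mixedlm("y ~ 1", df, groups=df["g"]).fit(reml=True)
    assert mu == pytest.approx(m.params.iloc[0], abs=1e-4)
    assert tau2 == pytest.approx(float(m.cov_re.iloc[0, 0]), abs=1e-3)
    assert sigma2 == pytest.approx(m.scale, abs=1e-3)


def test_fit_rescaling_equivariance():
    rng = np.random.default_rng(4)
    y = rng.normal(0.3, 1.0, 60)
    studies = np.repeat(["A", "B", "C"], 20)
    mu1, se1, tau1, sig1, z1, p1 = fit_random_intercept(y, studies)
    c = 3.7
    mu2, se2, tau2, sig2, z2, p2 = fit_random_intercept(c * y, studies)
    assert mu2 == pytest.approx(c * mu1, rel=1e-5)
    assert np.sqrt(tau2) == pytest.approx(c * np.sqrt(tau1), abs=1e-5)
    assert np.sqrt(sig2) == pytest.approx(c * np.sqrt(sig1), rel=1e-5)
    assert z2 == pytest.approx(z1, rel=1e-5)
    assert p2 == pytest.approx(p1, rel=1e-5)


def test_fit_invariant_to_label_renaming_and_order():
    rng = np.random.default_rng(5)
    y = rng.normal(0, 1, 30)
    studies = np.array(["x"] * 10 + ["y"] * 10 + ["z"] * 10)
    out1 = fit_random_intercept(y, studies)
    perm = rng.permutation(30)
    renames = {"x": "S3", "y": "S1", "z": "S2"}
    out2 = fit_random_intercept(y[perm], np.array([renames[s] for s in studies[perm]]))
    assert out1[0] == pytest.approx(out2[0], abs=1e-8)
    assert out1[2] == pytest.approx(out2[2], abs=1e-8)


def test_fit_degenerate_constant_response():
    with pytest.warns(UserWarning, match="degenerate"):
        fit = fit_random_intercept_lmm(np.ones(10), np.repeat(["A", "B"], 5))
    assert fit.tau2 == 0.0 and fit.sigma2 == 0.0
    assert fit.beta[0] == pytest.approx(1.0)


def test_fit_matches_grid_search_oracle():
    """Profiled REML agrees with a brute-force restricted-likelihood grid
    search over the variance ratio on random instances."""
    rng = np.random.default_rng(6)
    for _ in range(10):
        k = rng.integers(3, 7)
        ns = rng.integers(4, 12, k)
        y = np.concatenate([rng.normal(rng.normal(0, 1), 1.0, n) for n in ns])
        studies = np.concatenate([[f"S{i}"] * n for i, n in enumerate(ns)])
        mu, se, tau2, sigma2, _, _ = fit_random_intercept(y, studies)
        from tests.oracles import lmm_grid_oracle

        mu_o, tau2_o, sigma2_o = lmm_grid_oracle(y, studies)
        assert mu == pytest.approx(mu_o, abs=1e-3)
        assert tau2 == pytest.approx(tau2_o, abs=1e-3 * (1 + tau2_o))
        assert sigma2 == pytest.approx(sigma2_o, abs=1e-3 * (1 + sigma2_o))


# --- end-to-end differential abundance -------------------------------------

def test_run_differential_abundance_alpha_zero_empty(small_cohorts):
    cohorts, _ = small_cohorts
    d = delta_clr(cohorts)
    res = run_differential_abundance(d)
    assert significant_features(res, alpha=0.0) == []
    frame = results_frame(res)
    assert np.all(frame["q"] >= frame["p"] - 1e-12)
    assert np.all(frame["tau2"] >= 0) and np.all(frame["sigma2"] >= 0)


def test_planted_module_recovery(small_cohorts):
    cohorts, truth = small_cohorts
    d = delta_clr(cohorts)
    res = run_differential_abundance(d)
    sig = significant_features(res, 0.05)
    hits = {r.feature_id for r in sig} & set(truth.module_features)
    assert len(hits) >= 0.8 * len(truth.module_features)
    for r in sig:
        if r.feature_id in truth.module_features:
            assert r.mu_hat < 0


def test_consistency_table_shape_and_flags(small_cohorts):
    cohorts, truth = small_cohorts
    d = delta_clr(cohorts)
    res = run_differential_abundance(d)
    tab = consistency_table(res, d)
    sig = significant_features(res, 0.05)
    assert len(tab) == len(sig) * 2  # 2 studies
    recovered = tab[tab["feature_id"].isin(truth.module_features)]
    assert recovered["unidirectional"].all()
    assert (recovered["mean_delta_clr"] < 0).all()
    empty = consistency_table(res, d, alpha=0.0)
    assert empty.empty
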