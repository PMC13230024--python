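"""Compositional co-occurrence networks and cross-cohort rewiring.

Correlations between features are inferred with SparCC, which corrects the
spurious negative bias that relative-abundance (compositional) data imposes
on naive correlation: per resample, per-sample fractions are drawn from a
Dirichlet posterior (counts + 1), log-ratio variances
``t_ab = var(log(x_a / x_b))`` are computed, basis variances are obtained by
solving the SparCC linear system under the sparsity assumption, and the
most strongly correlated pairs are iteratively excluded from the system.
The point estimate is the median over resamples.

Edges are retained at ``|r| >= 0.1`` and permutation ``p < 0.05``, with
positive and negative correlations kept as separate edge classes.  A
node-level rewiring score in [0, 1) compares a feature's within-module
absolute edge strength between two networks (e.g. baseline vs endpoint);
scores are combined across cohorts by a sample-size-weighted mean, with
scores above 0.12 flagged as strongly rewired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core_data import FeatureTable, filter_prevalence, relative_abundance


@dataclass
class CorrelationNetwork:
    feature_ids: list
    r: np.ndarray
    p: np.ndarray | None = None
    provenance: tuple = ("", "")  # (cohort id, condition)

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        if not np.allclose(r, r.T, atol=1e-9):
            raise ValueError("correlation matrix not symmetric")
        if np.any(np.abs(r) > 1 + 1e-9):
            raise ValueError("|r| exceeds 1")
        np.fill_diagonal(r, 1.0)
        self.r = np.clip(r, -1.0, 1.0)


@dataclass
class RewiringScores:
    per_cohort: pd.DataFrame  # features x cohorts
    combined: pd.Series
    high_threshold: float = 0.12

    @property
    def high_flag(self) -> pd.Series:
        return self.combined > self.high_threshold

    def ranked(self) -> pd.Series:
        return self.combined.sort_values(ascending=False)


def _dirichlet_fractions(rng, counts):
    out = np.empty(counts.shape, dtype=float)
    for i, row in enumerate(counts):
        out[i] = rng.dirichlet(row + 1.0)
    return out


def _variation_matrix(logf):
    C = np.cov(logf, rowvar=False)
    v = np.diag(C)
    return v[:, None] + v[None, :] - 2.0 * C


def _basis_correlations(T, include, n_exclusion_iters, exclusion_threshold):
    """Solve the SparCC system, iteratively excluding the strongest pair."""
    D = T.shape[0]
    E = include.astype(float).copy()
    np.fill_diagonal(E, 0.0)
    r = None
    for _ in range(n_exclusion_iters + 1):
        deg = E.sum(axis=1)
        M = np.diag(deg) + E
        t = (E * T).sum(axis=1)
        try:
            omega = np.linalg.solve(M, t)
        except np.linalg.LinAlgError:
            break
        bad = omega <= 0
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} basis variance(s) non-positive; clamped"
            )
            omega = np.where(bad, 1e-10, omega)
        denom = 2.0 * np.sqrt(np.outer(omega, omega))
        r = np.clip((omega[:, None] + omega[None, :] - T) / denom, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        cand = np.abs(r) * (E > 0)
        np.fill_diagonal(cand, 0.0)
        if cand.max() < exclusion_threshold:
            break
        a, b = np.unravel_index(np.argmax(cand), cand.shape)
        E[a, b] = E[b, a] = 0.0
        if (E.sum(axis=1) < 2).any():  # keep the system identifiable
            break
    return r


def sparcc(
    t: FeatureTable,
    n_resamples: int = 20,
    n_exclusion_iters: int = 10,
    exclusion_threshold: float = 0.1,
    seed: int = 0,
    min_prevalence: float = 0.10,
    provenance: tuple = ("", ""),
) -> CorrelationNetwork:
    """SparCC correlation inference on a count table.

    Features observed in fewer than ``min_prevalence`` of samples are
    excluded before inference.  Requires >= 4 features (basis variances are
    unidentifiable below that) and is deterministic for a given seed.
    """
    ft = filter_prevalence(t, min_prevalence)
    D = ft.shape[1]
    if D < 4:
        raise ValueError(f"need >= 4 features after prevalence filter, got {D}")
    counts = ft.matrix().astype(float)
    rng = np.random.default_rng(seed)
    include = np.ones((D, D), dtype=bool)
    estimates = []
    for _ in range(n_resamples):
        f = _dirichlet_fractions(rng, counts)
        T = _variation_matrix(np.log(f))
        r = _basis_correlations(T, include, n_exclusion_iters, exclusion_threshold)
        if r is not None:
            estimates.append(r)
    if not estimates:
        raise RuntimeError("SparCC failed on every resample")
    r_med = np.median(np.array(estimates), axis=0)
    r_med = (r_med + r_med.T) / 2.0
    return CorrelationNetwork(
        feature_ids=ft.feature_ids, r=np.clip(r_med, -1, 1), provenance=provenance
    )


def permutation_pvalues(
    t: FeatureTable,
    r_obs: CorrelationNetwork,
    n_perm: int = 100,
    seed: int = 0,
    n_exclusion_iters: int = 10,
    exclusion_threshold: float = 0.1,
) -> np.ndarray:
    """Two-sided permutation p-values for SparCC correlations.

    Each permutation shuffles every feature's counts independently across
    samples (destroying all pairwise association while preserving marginal
    distributions) and recomputes the SparCC point estimate with a single
    resample.  Add-one rule: p is never exactly 0.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    sub = t.select_features(r_obs.feature_ids)
    counts = sub.matrix().astype(float)
    n, D = counts.shape
    rng = np.random.default_rng(seed)
    abs_obs = np.abs(r_obs.r)
    include = np.ones((D, D), dtype=bool)
    exceed = np.zeros((D, D))
    for _ in range(n_perm):
        perm = counts.copy()
        for j in range(D):
            rng.shuffle(perm[:, j])
        f = _dirichlet_fractions(rng, perm)
        T = _variation_matrix(np.log(f))
        r = _basis_correlations(T, include, n_exclusion_iters, exclusion_threshold)
        exceed += np.abs(r) >= abs_obs - 1e-12
    p = (1.0 + exceed) / (1.0 + n_perm)
    p = np.minimum(p, 1.0)
    np.fill_diagonal(p, 1.0)
    r_obs.p = p
    return p


def filter_edges(
    net: CorrelationNetwork, min_abs_r: float = 0.1, max_p: float = 0.05
) -> pd.DataFrame:
    """Edge list of pairs with ``|r| >= min_abs_r`` and ``p < max_p``.

    ``min_abs_r`` is inclusive, ``max_p`` strict.  Positive and negative
    correlations are labeled as separate sign classes.
    """
    if net.p is None:
        raise ValueError("network has no p-values; run permutation_pvalues first")
    feats = net.feature_ids
    rows = []
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            r = net.r[i, j]
            p = net.p[i, j]
            if abs(r) >= min_abs_r and p < max_p:
                rows.append(
                    {
                        "feature_a": feats[i],
                        "feature_b": feats[j],
                        "r": float(r),
                        "p": float(p),
                        "sign_class": "positive" if r > 0 else "negative",
                    }
                )
    return pd.DataFrame(rows, columns=["feature_a", "feature_b", "r", "p", "sign_class"])


def _edge_graph(edges: pd.DataFrame, nodes) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(nodes)
    for row in edges.itertuples():
        G.add_edge(row.feature_a, row.feature_b, weight=abs(row.r), r=row.r)
    return G


def detect_modules(edges: pd.DataFrame, nodes=None) -> list:
    """Greedy modularity communities on absolute edge weights.

    Returns a list of sorted feature-id lists partitioning the node set;
    edgeless features form singleton modules.  Deterministic for a fixed
    node order.
    """
    if nodes is None:
        nodes = sorted(set(edges["feature_a"]) | set(edges["feature_b"]))
    G = _edge_graph(edges, nodes)
    if G.number_of_edges() == 0:
        return [[n] for n in sorted(G.nodes)]
    comms = nx.community.greedy_modularity_communities(G, weight="weight")
    modules = [sorted(c) for c in comms]
    modules.sort(key=lambda m: (-len(m), m[0]))
    return modules


def _within_module_strength(edges: pd.DataFrame, partition) -> pd.Series:
    module_of = {f: i for i, mod in enumerate(partition) for f in mod}
    strength = {f: 0.0 for f in module_of}
    for row in edges.itertuples():
        a, b = row.feature_a, row.feature_b
        if module_of.get(a) is not None and module_of.get(a) == module_of.get(b):
            strength[a] += abs(row.r)
            strength[b] += abs(row.r)
    return pd.Series(strength)


def rewiring_score(netA: pd.DataFrame, netB: pd.DataFrame, partition) -> pd.Series:
    """Per-feature topology-change score between two edge lists.

    With ``s_A(i)`` / ``s_B(i)`` the within-module absolute edge strength of
    feature i in the two networks (module membership from ``partition``,
    typically computed on the union graph):

        score_i = |s_B - s_A| / (s_A + s_B + 1e-9)   in [0, 1)
    """
    sA = _within_module_strength(netA, partition)
    sB = _within_module_strength(netB, partition)
    idx = sA.index.union(sB.index)
    sA = sA.reindex(idx, fill_value=0.0)
    sB = sB.reindex(idx, fill_value=0.0)
    return (sB - sA).abs() / (sA + sB + 1e-9)


def combine_rewiring(per_cohort_scores: dict, cohort_sizes: dict) -> RewiringScores:
    """Sample-size-weighted mean of per-cohort rewiring scores."""
    if not per_cohort_scores:
        raise ValueError("need at least one cohort")
    df = pd.DataFrame(per_cohort_scores).fillna(0.0)
    w = np.array([cohort_sizes[c] for c in df.columns], dtype=float)
    if w.sum() <= 0:
        raise ValueError("cohort sizes must be positive")
    combined = pd.Series(df.to_numpy() @ (w / w.sum()), index=df.index)
    return RewiringScores(per_cohort=df, combined=combined)


def core_subnetwork(
    edges: pd.DataFrame,
    mean_abundance: pd.Series,
    rewiring: RewiringScores,
    depleted,
    n_core: int = 10,
) -> tuple:
    """Driver/depleted subgraph: top ``n_core`` most abundant features among
    those with the maximal rewiring score, plus the depleted set.

    Returns (node table, induced edge table).  Ties in rewiring score fall
    back to abundance order; fewer than ``n_core`` maximal-score features
    triggers a warning and all are taken.
    """
    combined = rewiring.combined
    max_score = combined.max()
    candidates = combined[combined >= max_score - 1e-12].index
    ranked = (
        mean_abundance.reindex(candidates)
        .fillna(0.0)
        .sort_values(ascending=False, kind="stable")
    )
    if len(ranked) < n_core:
        warnings.warn(
            f"only {len(ranked)} feature(s) at the maximal rewiring score; taking all"
        )
    drivers = list(ranked.index[:n_core])
    depleted = [f for f in depleted if f not in drivers]
    nodes = pd.DataFrame(
        [{"feature_id": f, "role": "driver"} for f in drivers]
        + [{"feature_id": f, "role": "depleted"} for f in depleted],
        columns=["feature_id", "role"],
    )
    member = set(nodes["feature_id"])
    induced = edges[
        edges["feature_a"].isin(member) & edges["feature_b"].isin(member)
    ].reset_index(drop=True)
    return nodes, induced


def mean_relative_abundance(t: FeatureTable) -> pd.Series:
    """Per-feature mean relative abundance across samples."""
    return relative_abundance(t).mean(axis=0)
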