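"""Alpha and beta diversity, paired within-subject distances, and PCoA.

Conventions: Shannon entropy is reported in bits (log2); Faith's PD includes
the path to the root; weighted UniFrac is unnormalized (the normalized
variant is available behind a flag); Jaccard is presence/absence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio import DistanceMatrix as _SkbioDM
from skbio.diversity import beta_diversity as _skbio_beta
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd

from .core_data import FeatureTable, SampleMetadata, pair_samples

ALPHA_METRICS = ("shannon", "observed_features", "faith_pd")
BETA_METRICS = ("bray_curtis", "jaccard", "unweighted_unifrac", "weighted_unifrac")


def shannon(counts) -> float:
    """Shannon entropy in bits of the count vector's proportions."""
    x = np.asarray(counts, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero count vector")
    p = x[x > 0] / total
    return float(-(p * np.log2(p)).sum())


def observed_features(counts) -> int:
    """Number of features with a strictly positive count."""
    return int((np.asarray(counts) > 0).sum())


def faith_pd(counts, feature_ids, tree: TreeNode) -> float:
    """Faith's phylogenetic diversity (root-inclusive).

    Sum of branch lengths of the minimal subtree connecting the observed
    features and the root.
    """
    x = np.asarray(counts)
    observed = [f for f, c in zip(feature_ids, x) if c > 0]
    leaves = {lf.name for lf in tree.tips()}
    missing = sorted(set(observed) - leaves)
    if missing:
        raise ValueError(f"features absent from tree: {missing}")
    if not observed:
        return 0.0
    return float(_skbio_faith_pd(x, taxa=list(feature_ids), tree=tree))


def alpha_table(t: FeatureTable, tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample alpha diversity (shannon, observed_features, faith_pd)."""
    rows = {}
    feats = t.feature_ids
    for sid, row in zip(t.sample_ids, t.matrix()):
        entry = {
            "shannon": shannon(row),
            "observed_features": observed_features(row),
        }
        if tree is not None:
            entry["faith_pd"] = faith_pd(row, feats, tree)
        rows[sid] = entry
    return pd.DataFrame.from_dict(rows, orient="index")


class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity matrix."""

    def __init__(self, data: np.ndarray, ids, metric: str):
        data = np.asarray(data, dtype=float)
        if not np.allclose(data, data.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        np.fill_diagonal(data, 0.0)
        if np.any(data < 0):
            raise ValueError("negative distances")
        self.data = data
        self.ids = list(ids)
        self.metric = metric
        self._pos = {s: i for i, s in enumerate(self.ids)}

    def between(self, a, b) -> float:
        return float(self.data[self._pos[a], self._pos[b]])

    def filter(self, ids) -> "DistanceMatrix":
        idx = [self._pos[s] for s in ids]
        return DistanceMatrix(self.data[np.ix_(idx, idx)], ids, self.metric)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def beta_distance(
    t: FeatureTable,
    metric: str,
    tree: TreeNode | None = None,
    normalized_weighted: bool = False,
) -> DistanceMatrix:
    """Pairwise beta-diversity distances between all samples of ``t``."""
    if metric not in BETA_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {BETA_METRICS}")
    arr = t.matrix().astype(float)
    ids = t.sample_ids
    if metric == "bray_curtis":
        d = squareform(pdist(arr, metric="braycurtis"))
        d = np.nan_to_num(d)
    elif metric == "jaccard":
        d = squareform(pdist(arr > 0, metric="jaccard"))
    else:
        if tree is None:
            raise ValueError(f"{metric} requires a phylogenetic tree")
        leaves = {lf.name for lf in tree.tips()}
        missing = sorted(set(t.feature_ids) - leaves)
        if missing:
            raise ValueError(f"features absent from tree: {missing[:5]}")
        skbio_metric = metric
        kwargs = {}
        if metric == "weighted_unifrac":
            kwargs["normalized"] = normalized_weighted
        dm = _skbio_beta(
            skbio_metric, arr, ids=ids, taxa=t.feature_ids, tree=tree, **kwargs
        )
        d = dm.data
    return DistanceMatrix(d, ids, metric)


def paired_beta_distance(
    t: FeatureTable,
    m: SampleMetadata,
    metric: str,
    tree: TreeNode | None = None,
) -> pd.DataFrame:
    """Within-subject baseline-vs-endpoint distance, one row per complete pair.

    The returned frame carries subject and study ids so that the paired
    distances can be compared across intervention classes downstream.
    """
    pairs = pair_samples(m)
    dm = beta_distance(t, metric, tree=tree)
    rows = [
        {
            "subject_id": subj,
            "study_id": study,
            "metric": metric,
            "distance": dm.between(b, e),
        }
        for b, e, subj, study in pairs
    ]
    return pd.DataFrame(rows, columns=["subject_id", "study_id", "metric", "distance"])


def pcoa(D: DistanceMatrix, k: int = 2):
    """Classical (Torgerson) principal coordinates of a distance matrix.

    Gower-centers ``-0.5 * D**2`` and eigendecomposes it.  Coordinates are
    returned for the top ``k`` axes by descending eigenvalue; the full
    eigenvalue spectrum — including any negative eigenvalues, which signal a
    non-Euclidean matrix — is returned unmodified.

    Returns
    -------
    (coordinates, eigenvalues) : (pandas.DataFrame, numpy.ndarray)
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d2 = D.data**2
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = min(k, n)
    coords = evecs[:, :k] * np.sqrt(np.clip(evals[:k], 0.0, None))
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(coords, index=D.ids, columns=cols), evals
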