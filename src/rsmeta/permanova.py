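"""Distance-based variance decomposition (PERMANOVA).

Two permutation schemes are provided: unrestricted label permutation (for
study-level clustering of baseline samples) and a repeated-measures scheme
whose permutations are restricted within subject blocks of two samples —
i.e. independent baseline/endpoint label swaps per subject, the only
permutations that preserve the pairing.  When the restricted scheme has
``2**n_subjects <= n_perm`` possible relabelings, all of them are
enumerated and the p-value is exact; otherwise Monte-Carlo sampling is used
with the add-one convention ``p = (1 + #{F* >= F}) / (1 + n_perm)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diversity import DistanceMatrix


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_perm: int
    scheme: str  # "unrestricted" | "within_subject"
    exact: bool = False


def _group_indicator(groups) -> tuple:
    groups = np.asarray(groups)
    labels, inv = np.unique(groups, return_inverse=True)
    Z = np.zeros((len(labels), groups.size))
    Z[inv, np.arange(groups.size)] = 1.0
    return labels, Z


def pseudo_f(D: DistanceMatrix, groups) -> tuple:
    """PERMANOVA pseudo-F and R2 for a single grouping factor.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within sums the analogous per-group
    terms; F = (SS_between/(a-1)) / (SS_within/(n-a)).
    """
    d2 = D.data**2
    n = d2.shape[0]
    labels, Z = _group_indicator(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    ss_total = d2.sum() / (2.0 * n)
    if ss_total == 0:
        raise ValueError("zero total sum of squares: all samples identical")
    sizes = Z.sum(axis=1)
    ss_within = float(sum((Z[g] @ d2 @ Z[g]) / (2.0 * sizes[g]) for g in range(len(labels))))
    ss_between = ss_total - ss_within
    a = len(labels)
    F = (ss_between / (a - 1)) / (ss_within / (n - a))
    return float(F), float(ss_between / ss_total)


def _f_two_groups_batch(d2: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Pseudo-F for a batch of binary group indicators (rows of Z).

    ``Z`` is (P, n) with entries in {0,1}; group sizes must be constant
    across rows is NOT required.
    """
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    n1 = Z.sum(axis=1)
    n0 = n - n1
    q1 = np.einsum("pi,ij,pj->p", Z, d2, Z)
    W = 1.0 - Z
    q0 = np.einsum("pi,ij,pj->p", W, d2, W)
    ss_within = q1 / (2.0 * n1) + q0 / (2.0 * n0)
    ss_between = ss_total - ss_within
    return (ss_between / 1.0) / (ss_within / (n - 2))


def rm_permanova(
    D: DistanceMatrix,
    groups,
    subjects,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Repeated-measures PERMANOVA with permutations restricted within subjects.

    Each subject block must contain exactly two samples with the two
    distinct group labels (baseline/endpoint).  The null distribution swaps
    the two labels independently within each subject.
    """
    groups = np.asarray(groups)
    subjects = np.asarray(subjects)
    glabels = np.unique(groups)
    if len(glabels) != 2:
        raise ValueError("repeated-measures scheme requires exactly 2 group labels")
    subj_labels, subj_inv = np.unique(subjects, return_inverse=True)
    pair_idx = []
    for s in range(len(subj_labels)):
        idx = np.nonzero(subj_inv == s)[0]
        if idx.size != 2:
            raise ValueError(
                f"subject {subj_labels[s]!r} has {idx.size} samples; blocks of 2 required"
            )
        if groups[idx[0]] == groups[idx[1]]:
            raise ValueError(
                f"subject {subj_labels[s]!r} has identical group labels at both samples"
            )
        pair_idx.append(idx)
    pair_idx = np.array(pair_idx)  # (S, 2)
    S = pair_idx.shape[0]
    d2 = D.data**2
    n = d2.shape[0]

    z_obs = (groups == glabels[1]).astype(float)
    F_obs = _f_two_groups_batch(d2, z_obs[None, :])[0]
    _, R2 = pseudo_f(D, groups)

    exact = 2**S <= n_perm
    if exact:
        P = 2**S
        flips = ((np.arange(P)[:, None] >> np.arange(S)[None, :]) & 1).astype(bool)
    else:
        rng = np.random.default_rng(seed)
        flips = rng.integers(0, 2, size=(n_perm, S)).astype(bool)
        P = n_perm
    Z = np.broadcast_to(z_obs, (P, n)).copy()
    a = pair_idx[:, 0]
    b = pair_idx[:, 1]
    za, zb = z_obs[a], z_obs[b]
    Za = np.where(flips, zb[None, :], za[None, :])
    Zb = np.where(flips, za[None, :], zb[None, :])
    Z[:, a] = Za
    Z[:, b] = Zb
    F_perm = _f_two_groups_batch(d2, Z)
    tol = 1e-12
    if exact:
        p = float((F_perm >= F_obs - tol).sum()) / P
    else:
        p = (1.0 + float((F_perm >= F_obs - tol).sum())) / (1.0 + n_perm)
    return PermanovaResult(
        pseudo_F=float(F_obs),
        R2=R2,
        p=p,
        n_perm=P if exact else n_perm,
        scheme="within_subject",
        exact=exact,
    )


def study_variance(
    D: DistanceMatrix,
    study_labels,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Unrestricted PERMANOVA of study identity (variance explained by study)."""
    study_labels = np.asarray(study_labels)
    if len(np.unique(study_labels)) < 2:
        raise ValueError("need at least 2 studies")
    F_obs, R2 = pseudo_f(D, study_labels)
    rng = np.random.default_rng(seed)
    d2 = D.data**2
    count = 0
    labels = study_labels.copy()
    for _ in range(n_perm):
        rng.shuffle(labels)
        F, _ = _pseudo_f_raw(d2, labels)
        if F >= F_obs - 1e-12:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return PermanovaResult(
        pseudo_F=float(F_obs),
        R2=R2,
        p=p,
        n_perm=n_perm,
        scheme="unrestricted",
    )


def _pseudo_f_raw(d2: np.ndarray, groups) -> tuple:
    n = d2.shape[0]
    labels, Z = _group_indicator(groups)
    ss_total = d2.sum() / (2.0 * n)
    sizes = Z.sum(axis=1)
    ss_within = float(
        sum((Z[g] @ d2 @ Z[g]) / (2.0 * sizes[g]) for g in range(len(labels)))
    )
    ss_between = ss_total - ss_within
    a = len(labels)
    F = (ss_between / (a - 1)) / (ss_within / (n - a))
    return float(F), float(ss_between / ss_total)
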