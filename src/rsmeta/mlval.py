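"""Subject-aware classifier validation across cohorts.

All evaluation schemes keep both samples of a subject on the same side of
every train/test split, so reported AUROCs measure discrimination of
intervention (or disease) state rather than subject identity.  Three
schemes are provided: within-study k-fold cross-validation (CV),
cross-study validation (CSV: train on one study, test on each other), and
leave-one-study-out (LOSO: train on the pooled remainder, test on the
held-out study).  The classifier is a 500-tree random forest with library
defaults; features are CLR-transformed counts by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .core_data import CohortSet, FeatureTable, SampleMetadata, clr_transform

POSITIVE = {"paired": "endpoint"}  # cross-sectional positive label passed explicitly


@dataclass
class FoldSpec:
    fold_id: int
    train_samples: list
    test_samples: list

    def __post_init__(self):
        if set(self.train_samples) & set(self.test_samples):
            raise ValueError("train and test overlap")


@dataclass
class EvalResult:
    scheme: str  # "cv" | "csv" | "loso"
    train_scope: str
    test_scope: str
    auc: float
    n_test: int


def auroc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUROC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def subject_folds(m: SampleMetadata, k: int = 5, seed: int = 0) -> list:
    """Deal subjects (not samples) into k folds after a seeded shuffle."""
    subjects = sorted(m.table["subject_id"].unique())
    if len(subjects) < k:
        raise ValueError(f"need >= {k} subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    rng.shuffle(subjects)
    assignment = {s: i % k for i, s in enumerate(subjects)}
    folds = []
    by_subject = m.table.groupby("subject_id")["sample_id"].apply(list)
    for f in range(k):
        test_subj = [s for s in subjects if assignment[s] == f]
        train_subj = [s for s in subjects if assignment[s] != f]
        folds.append(
            FoldSpec(
                fold_id=f,
                train_samples=sorted(sid for s in train_subj for sid in by_subject[s]),
                test_samples=sorted(sid for s in test_subj for sid in by_subject[s]),
            )
        )
    return folds


def _features(table: FeatureTable, kind: str) -> pd.DataFrame:
    if kind == "clr":
        return clr_transform(table)
    if kind == "relative":
        from .core_data import relative_abundance

        return relative_abundance(table)
    raise ValueError(f"unknown feature kind {kind!r}")


def _labels(meta: SampleMetadata, positive: str) -> pd.Series:
    cond = meta.condition_of()
    return (cond == positive).astype(int)


def _rf(seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)


def _fit_score(X_train, y_train, X_test, seed):
    clf = _rf(seed)
    clf.fit(X_train, y_train)
    return clf.predict_proba(X_test)[:, list(clf.classes_).index(1)]


def _assert_no_subject_leakage(meta: SampleMetadata, train_ids, test_ids):
    subj = meta.table.set_index("sample_id")["subject_id"]
    overlap = set(subj.loc[list(train_ids)]) & set(subj.loc[list(test_ids)])
    if overlap:
        raise AssertionError(f"subject leakage across the split: {sorted(overlap)[:3]}")


def within_study_cv(
    c: CohortSet,
    feature_kind: str = "clr",
    k: int = 5,
    seed: int = 0,
    positive: str = "endpoint",
) -> list:
    """Per-study subject-blocked k-fold CV; held-out scores pooled into one AUC."""
    results = []
    for sid, (table, meta) in c.items():
        X = _features(table, feature_kind)
        y = _labels(meta, positive)
        folds = subject_folds(meta, k=k, seed=seed)
        scores, labels = [], []
        for fold in folds:
            _assert_no_subject_leakage(meta, fold.train_samples, fold.test_samples)
            s = _fit_score(
                X.loc[fold.train_samples],
                y.loc[fold.train_samples],
                X.loc[fold.test_samples],
                seed,
            )
            scores.append(s)
            labels.append(y.loc[fold.test_samples].to_numpy())
        auc = auroc(np.concatenate(scores), np.concatenate(labels))
        results.append(
            EvalResult(
                scheme="cv", train_scope=sid, test_scope=sid, auc=auc, n_test=len(y)
            )
        )
    return results


def cross_study_validation(
    c: CohortSet,
    feature_kind: str = "clr",
    seed: int = 0,
    positive: str = "endpoint",
) -> list:
    """Train on each study once; evaluate on every other study."""
    sids = c.study_ids
    if len(sids) < 2:
        raise ValueError("need >= 2 studies")
    feats = {sid: _features(t, feature_kind) for sid, (t, _) in c.items()}
    labels = {sid: _labels(m, positive) for sid, (_, m) in c.items()}
    results = []
    for train_sid in sids:
        clf = _rf(seed)
        clf.fit(feats[train_sid], labels[train_sid])
        pos_col = list(clf.classes_).index(1)
        for test_sid in sids:
            if test_sid == train_sid:
                continue
            s = clf.predict_proba(feats[test_sid])[:, pos_col]
            results.append(
                EvalResult(
                    scheme="csv",
                    train_scope=train_sid,
                    test_scope=test_sid,
                    auc=auroc(s, labels[test_sid]),
                    n_test=len(labels[test_sid]),
                )
            )
    return results


def loso(
    c: CohortSet,
    feature_kind: str = "clr",
    seed: int = 0,
    positive: str = "endpoint",
    feature_subset=None,
) -> list:
    """Leave-one-study-out: train on the pooled remainder, test the held-out study.

    ``feature_subset`` restricts the model to the named features *after* the
    transform, so e.g. a module's relative abundances stay on the
    whole-community scale.
    """
    sids = c.study_ids
    if len(sids) < 2:
        raise ValueError("need >= 2 studies")
    feats = {sid: _features(t, feature_kind) for sid, (t, _) in c.items()}
    if feature_subset is not None:
        cols = [f for f in feature_subset if f in next(iter(feats.values())).columns]
        feats = {sid: X[cols] for sid, X in feats.items()}
    labels = {sid: _labels(m, positive) for sid, (_, m) in c.items()}
    subj = {
        sid: set(m.table["subject_id"]) for sid, (_, m) in c.items()
    }
    results = []
    for held in sids:
        train_sids = [s for s in sids if s != held]
        X_train = pd.concat([feats[s] for s in train_sids])
        y_train = pd.concat([labels[s] for s in train_sids])
        train_subjects = set().union(*(subj[s] for s in train_sids))
        if train_subjects & subj[held]:
            raise AssertionError("held-out subjects appear in training data")
        s = _fit_score(X_train, y_train, feats[held], seed)
        results.append(
            EvalResult(
                scheme="loso",
                train_scope="+".join(train_sids),
                test_scope=held,
                auc=auroc(s, labels[held]),
                n_test=len(labels[held]),
            )
        )
    return results


def stratify_by_class(results: list, class_map: dict) -> pd.DataFrame:
    """Group LOSO results by intervention class (e.g. RS2 vs RS4).

    Classes represented by a single study are flagged ``excluded`` and not
    summarized with a mean.
    """
    missing = {r.test_scope for r in results} - set(class_map)
    if missing:
        raise ValueError(f"class_map missing studies: {sorted(missing)}")
    rows = []
    by_class: dict = {}
    for r in results:
        by_class.setdefault(class_map[r.test_scope], []).append(r)
    for cls, rs in sorted(by_class.items()):
        excluded = len(rs) < 2
        rows.append(
            {
                "class": cls,
                "n_studies": len(rs),
                "mean_auc": np.nan if excluded else float(np.mean([r.auc for r in rs])),
                "excluded": excluded,
            }
        )
    return pd.DataFrame(rows)


def results_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scheme": r.scheme,
                "train_scope": r.train_scope,
                "test_scope": r.test_scope,
                "auc": r.auc,
                "n_test": r.n_test,
            }
            for r in results
        ]
    )
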