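"""Shared data model and preprocessing for cross-cohort microbiome analyses.

The currency of every downstream stage is a :class:`FeatureTable` of raw
integer counts (samples x features), a :class:`SampleMetadata` table carrying
study / subject / condition labels, and optionally a rooted phylogeny over the
features.  This module also owns the preprocessing conventions used
throughout the pipeline:

* samples with fewer than 1,000 reads are dropped before any analysis;
* rarefaction (subsampling without replacement) is applied only for
  alpha/beta-diversity work — differential abundance operates on raw counts;
* features seen in fewer than 10% of samples are dropped before
  differential-abundance testing;
* the centered log-ratio (CLR) transform uses a pseudocount of 1 and the
  natural logarithm.
"""

from __future__ import annotations

import io
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

PAIRED_CONDITIONS = ("baseline", "endpoint")
CROSS_SECTIONAL_CONDITIONS = ("HC", "CD", "UC")


class FormatError(ValueError):
    """Raised when an on-disk table violates the format contract."""


class ValidationError(ValueError):
    """Raised when data content violates a domain invariant."""


@dataclass
class FeatureTable:
    """Non-negative integer count matrix indexed by (sample, feature).

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows are samples, columns are features.  Entries must be
        non-negative integers; row and column labels must be unique.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            raise FormatError("duplicate sample ids in feature table")
        if df.columns.has_duplicates:
            raise FormatError("duplicate feature ids in feature table")
        arr = df.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise FormatError("non-numeric entry in feature table")
            if np.any(arr < 0):
                r, c = np.argwhere(arr < 0)[0]
                raise FormatError(
                    f"negative count at sample {df.index[r]!r}, "
                    f"feature {df.columns[c]!r}"
                )
            if not np.allclose(arr, np.round(arr)):
                r, c = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise FormatError(
                    f"non-integral count at sample {df.index[r]!r}, "
                    f"feature {df.columns[c]!r}"
                )
        self.counts = df.astype(np.int64)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple:
        return self.counts.shape

    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy()

    def select_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.counts.loc[list(sample_ids)])

    def select_features(self, feature_ids) -> "FeatureTable":
        return FeatureTable(self.counts[list(feature_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTable) and self.counts.equals(other.counts)


@dataclass
class SampleMetadata:
    """Per-sample study, subject and condition labels.

    ``mode`` is ``"paired"`` (condition is a timepoint, baseline/endpoint) or
    ``"cross_sectional"`` (condition is a diagnosis, HC/CD/UC).
    """

    table: pd.DataFrame
    mode: str

    CONDITION_COL = {"paired": "timepoint", "cross_sectional": "diagnosis"}

    def __post_init__(self) -> None:
        if self.mode not in self.CONDITION_COL:
            raise ValidationError(f"unknown metadata mode {self.mode!r}")
        cond = self.CONDITION_COL[self.mode]
        required = ["sample_id", "study_id", "subject_id", cond]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        df = self.table[required].astype(str).copy()
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        allowed = (
            PAIRED_CONDITIONS if self.mode == "paired" else CROSS_SECTIONAL_CONDITIONS
        )
        bad = sorted(set(df[cond]) - set(allowed))
        if bad:
            raise ValidationError(
                f"unknown {cond} labels {bad}; allowed: {list(allowed)}"
            )
        if self.mode == "paired":
            # a subject id may recur across studies; pairing is within study
            dup = df.duplicated(subset=["study_id", "subject_id", cond])
            if dup.any():
                row = df.loc[dup].iloc[0]
                raise ValidationError(
                    f"subject {row['subject_id']!r} has more than one "
                    f"{row[cond]!r} sample"
                )
        self.table = df.reset_index(drop=True)

    @property
    def condition_col(self) -> str:
        return self.CONDITION_COL[self.mode]

    @property
    def sample_ids(self) -> list:
        return list(self.table["sample_id"])

    def condition_of(self) -> pd.Series:
        return self.table.set_index("sample_id")[self.condition_col]

    def select_samples(self, sample_ids) -> "SampleMetadata":
        keep = self.table[self.table["sample_id"].isin(set(sample_ids))]
        return SampleMetadata(keep.copy(), self.mode)


@dataclass
class CohortSet:
    """One feature table + metadata per study, with an optional shared tree."""

    studies: dict  # study_id -> (FeatureTable, SampleMetadata)
    tree: TreeNode | None = None

    def __post_init__(self) -> None:
        for sid, (table, meta) in self.studies.items():
            if set(table.sample_ids) != set(meta.sample_ids):
                raise ValidationError(
                    f"study {sid!r}: table and metadata sample ids differ"
                )

    @property
    def study_ids(self) -> list:
        return list(self.studies)

    @property
    def mode(self) -> str:
        modes = {m.mode for _, m in self.studies.values()}
        if len(modes) > 1:
            raise ValidationError(f"mixed metadata modes in cohort set: {modes}")
        return modes.pop() if modes else "paired"

    def items(self):
        return self.studies.items()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_feature_table(path) -> FeatureTable:
    """Read a TSV count table (first column sample ids, header feature ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return FeatureTable(df)


def write_feature_table(t: FeatureTable, path) -> None:
    t.counts.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path, mode: str) -> SampleMetadata:
    """Read a TSV metadata table for ``mode`` in {paired, cross_sectional}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleMetadata(df, mode)


def write_metadata(m: SampleMetadata, path) -> None:
    m.table.to_csv(path, sep="\t", index=False)


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree with branch lengths on every non-root edge."""
    tree = TreeNode.read(str(path), format="newick")
    root = tree.root()
    if len(root.children) > 2:
        raise ValidationError(
            "tree root is multifurcating (unrooted convention); re-root the "
            "tree, e.g. with an outgroup, before use"
        )
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValidationError(
                f"branch leading to {node.name or '<internal>'} has no length"
            )
        if node.length < 0:
            raise ValidationError("negative branch length")
    names = [lf.name for lf in tree.tips()]
    if len(names) != len(set(names)):
        raise ValidationError("duplicate leaf labels")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Filtering / rarefaction / pairing
# ---------------------------------------------------------------------------

def filter_min_depth(t: FeatureTable, min_total: int = 1000) -> FeatureTable:
    """Drop samples whose total count is below ``min_total`` (default 1,000)."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    sums = t.counts.sum(axis=1)
    keep = sums[sums >= min_total].index
    if len(keep) == 0:
        warnings.warn("all samples below depth threshold; empty table returned")
    return FeatureTable(t.counts.loc[keep])


def filter_prevalence(t: FeatureTable, min_fraction: float = 0.10) -> FeatureTable:
    """Keep features detected (count > 0) in >= ceil(min_fraction * n) samples."""
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    n = t.shape[0]
    need = math.ceil(min_fraction * n)
    prev = (t.counts > 0).sum(axis=0)
    keep = prev[prev >= need].index
    return FeatureTable(t.counts[keep])


def rarefy(t: FeatureTable, depth: int = 1000, seed: int | None = None) -> FeatureTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Rows below ``depth`` are an error: run :func:`filter_min_depth` first.
    Deterministic for a given ``seed``.
    """
    if seed is None:
        raise ValueError("rarefy requires an explicit seed for reproducibility")
    arr = t.matrix()
    sums = arr.sum(axis=1)
    low = np.nonzero(sums < depth)[0]
    if low.size:
        raise ValueError(
            f"{low.size} sample(s) below rarefaction depth {depth} "
            f"(e.g. {t.sample_ids[low[0]]!r}); run filter_min_depth first"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(arr)
    for i, row in enumerate(arr):
        if sums[i] == depth:
            out[i] = row
            continue
        # multivariate hypergeometric draw of `depth` reads from the row
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return FeatureTable(pd.DataFrame(out, index=t.counts.index, columns=t.counts.columns))


def pair_samples(m: SampleMetadata) -> list:
    """Return (baseline_id, endpoint_id, subject_id, study_id) per complete pair.

    Subjects lacking either timepoint are dropped; the number dropped is
    logged.  Pairing is within (study, subject).
    """
    if m.mode != "paired":
        raise ValidationError("pair_samples requires paired-mode metadata")
    pairs = []
    dropped = 0
    for (study, subject), grp in m.table.groupby(["study_id", "subject_id"], sort=True):
        tps = dict(zip(grp["timepoint"], grp["sample_id"]))
        if set(tps) == set(PAIRED_CONDITIONS):
            pairs.append((tps["baseline"], tps["endpoint"], subject, study))
        else:
            dropped += 1
    if dropped:
        logger.info("pair_samples: dropped %d incomplete subject(s)", dropped)
    return pairs


# ---------------------------------------------------------------------------
# Compositional transforms
# ---------------------------------------------------------------------------

def relative_abundance(t: FeatureTable) -> pd.DataFrame:
    """Row-normalize counts to proportions (rows sum to 1)."""
    arr = t.matrix().astype(float)
    sums = arr.sum(axis=1)
    if np.any(sums == 0):
        i = int(np.nonzero(sums == 0)[0][0])
        raise ValueError(f"sample {t.sample_ids[i]!r} has zero total count")
    return pd.DataFrame(
        arr / sums[:, None], index=t.counts.index, columns=t.counts.columns
    )


def clr_transform(t: FeatureTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform: ln(x + pc) minus the per-sample mean log.

    A pseudocount (default 1) handles structural zeros; rows of the result
    sum to zero.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    logs = np.log(t.matrix() + pseudocount)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=t.counts.index, columns=t.counts.columns)


# ---------------------------------------------------------------------------
# Cohort bookkeeping
# ---------------------------------------------------------------------------

def cohort_summary(c: CohortSet) -> pd.DataFrame:
    """Per-study and total counts of subjects / samples.

    Paired mode: columns ``n_subjects`` (complete pairs) and
    ``n_paired_samples``.  Cross-sectional mode: per-diagnosis sample counts
    plus ``total``.  The final row (``study_id == "Total"``) holds column sums.
    """
    rows = []
    if not c.studies:
        return pd.DataFrame(
            [{"study_id": "Total", "n_subjects": 0, "n_paired_samples": 0}]
        )
    mode = c.mode
    for sid, (_, meta) in c.items():
        if mode == "paired":
            pairs = pair_samples(meta)
            rows.append(
                {
                    "study_id": sid,
                    "n_subjects": len(pairs),
                    "n_paired_samples": 2 * len(pairs),
                }
            )
        else:
            diag = meta.table["diagnosis"]
            row = {"study_id": sid}
            for d in CROSS_SECTIONAL_CONDITIONS:
                row[f"n_{d}"] = int((diag == d).sum())
            row["total"] = int(len(diag))
            rows.append(row)
    df = pd.DataFrame(rows)
    total = {"study_id": "Total"}
    for col in df.columns:
        if col != "study_id":
            total[col] = int(df[col].sum())
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)
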