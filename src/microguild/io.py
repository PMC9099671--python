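"""Readers, writers, and the shared domain containers.

The pipeline's central objects are a samples × ASVs count table
(:class:`FeatureTable`), per-sample metadata (:class:`SampleFrame`), a rooted
phylogeny over the ASVs (a scikit-bio ``TreeNode``), and symmetric distance
matrices (scikit-bio ``DistanceMatrix``).  All file formats are plain text:
TSV tables (QIIME 2 export dialect, with an optional leading ``#OTU ID``
header cell) and single-tree Newick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.io.format.newick import NewickFormatError

__all__ = [
    "FeatureTable",
    "SampleFrame",
    "read_feature_table",
    "write_feature_table",
    "read_sample_frame",
    "write_sample_frame",
    "read_newick",
    "write_newick",
]

REQUIRED_METADATA_COLUMNS = ("sample_id", "subject_id", "group", "timepoint")


@dataclass(frozen=True)
class FeatureTable:
    """Non-negative integer counts, samples as rows, ASVs as columns.

    Invariants (enforced at construction): unique sample and feature ids,
    counts >= 0, and every sample has at least one positive count.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample id(s): {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature id(s): {dupes}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("feature table contains non-numeric values")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at sample {df.index[i]!r}, feature {df.columns[j]!r}"
            )
        empty = df.index[values.sum(axis=1) == 0].tolist()
        if empty:
            raise ValueError(f"sample(s) with all-zero counts: {empty}")
        object.__setattr__(self, "counts", df.astype(np.int64))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Counts divided by per-sample totals (rows sum to 1)."""
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    def filter_samples(self, keep: list[str]) -> "FeatureTable":
        missing = [s for s in keep if s not in self.counts.index]
        if missing:
            raise KeyError(f"unknown sample id(s): {missing}")
        return FeatureTable(self.counts.loc[keep])

    def filter_features(self, keep: list[str]) -> "FeatureTable":
        missing = [f for f in keep if f not in self.counts.columns]
        if missing:
            raise KeyError(f"unknown feature id(s): {missing}")
        return FeatureTable(self.counts.loc[:, keep])


@dataclass(frozen=True)
class SampleFrame:
    """Per-sample metadata: subject (mouse), group (genotype), timepoint,
    optional cage and body weight in grams."""

    data: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample_id(s): {dupes}")
        for col in ("subject_id", "group", "timepoint"):
            if col not in df.columns:
                raise ValueError(f"missing required metadata column: {col!r}")
        if "body_weight" in df.columns:
            weights = pd.to_numeric(df["body_weight"], errors="coerce")
            df = df.assign(body_weight=weights)
        object.__setattr__(self, "data", df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subjects(self, sample_ids: list[str] | None = None) -> pd.Series:
        sub = self.data["subject_id"]
        return sub if sample_ids is None else sub.loc[sample_ids]

    def groups(self, sample_ids: list[str] | None = None) -> pd.Series:
        g = self.data["group"]
        return g if sample_ids is None else g.loc[sample_ids]

    def timepoints(self, sample_ids: list[str] | None = None) -> pd.Series:
        t = self.data["timepoint"]
        return t if sample_ids is None else t.loc[sample_ids]

    def body_weights(self, sample_ids: list[str] | None = None) -> pd.Series:
        if "body_weight" not in self.data.columns:
            return pd.Series(np.nan, index=self.data.index, name="body_weight")
        w = self.data["body_weight"]
        return w if sample_ids is None else w.loc[sample_ids]

    def select(self, **criteria) -> list[str]:
        """Sample ids matching all column==value criteria."""
        mask = pd.Series(True, index=self.data.index)
        for col, val in criteria.items():
            mask &= self.data[col] == val
        return list(self.data.index[mask])


def read_feature_table(
    path: str | Path,
    orientation: Literal["samples", "features"] = "samples",
) -> FeatureTable:
    """Read a TSV count table.

    ``orientation`` states what the file's ROWS are; no guessing is done,
    because a silently transposed table is a classic microbiome bug.  A
    leading ``#OTU ID`` (or any ``#``-prefixed) header cell is tolerated.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    df.index = df.index.astype(str).rename(None)
    df.columns = df.columns.astype(str).rename(None)
    if orientation == "features":
        df = df.T
    elif orientation != "samples":
        raise ValueError(f"orientation must be 'samples' or 'features', got {orientation!r}")
    bad = df.apply(pd.to_numeric, errors="coerce")
    if bad.isna().any().any():
        i, j = np.argwhere(bad.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric count at sample {df.index[i]!r}, feature {df.columns[j]!r}"
        )
    return FeatureTable(bad)


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    orientation: Literal["samples", "features"] = "samples",
) -> None:
    df = table.counts if orientation == "samples" else table.counts.T
    label = "sample_id" if orientation == "samples" else "#OTU ID"
    df.to_csv(path, sep="\t", index_label=label)


def read_sample_frame(path: str | Path) -> SampleFrame:
    """Read TSV metadata with columns sample_id, subject_id, group,
    timepoint, and optional cage_id / body_weight (grams, blank allowed)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    for col in REQUIRED_METADATA_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required metadata column: {col!r}")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return SampleFrame(df)


def write_sample_frame(frame: SampleFrame, path: str | Path) -> None:
    frame.data.to_csv(path, sep="\t", index_label="sample_id")


def read_newick(path: str | Path) -> TreeNode:
    """Read a single rooted tree; absent branch lengths become 0 (warned)."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except NewickFormatError as exc:
        raise ValueError(f"unparseable newick in {path}: {exc}") from exc
    names = [tip.name for tip in tree.tips()]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate leaf name(s) in tree: {dupes}")
    n_missing = 0
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise ValueError(f"negative branch length at node {node.name!r}")
    # the root itself always lacks a parent branch; only warn beyond that
    if n_missing > 1:
        warnings.warn(
            f"{n_missing - 1} branch(es) had no length; treated as 0",
            stacklevel=2,
        )
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")
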