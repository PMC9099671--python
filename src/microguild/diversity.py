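"""Rarefaction, alpha diversity, weighted UniFrac, PCoA, and
distance-to-reference summaries.

Conventions: Shannon entropy in bits (log base 2, configurable); weighted
UniFrac is the unnormalized variant ``sum_b l_b * |P_A(b) - P_B(b)|``;
samples below the rarefaction depth are dropped, not resampled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .io import FeatureTable

__all__ = [
    "Ordination",
    "rarefy",
    "shannon",
    "observed_features",
    "weighted_unifrac",
    "unifrac_matrix",
    "pcoa",
    "distances_to_group",
]

logger = logging.getLogger(__name__)


def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample every sample WITHOUT replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped with a logged
    warning; a sample already at ``depth`` is returned unchanged.
    Deterministic given ``seed``.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_sums()
    kept_rows = []
    kept_ids = []
    for sid in table.sample_ids:
        row = table.counts.loc[sid].to_numpy()
        total = int(totals[sid])
        if total < depth:
            logger.warning(
                "sample %s has %d reads < rarefaction depth %d; dropped",
                sid, total, depth,
            )
            continue
        if total == depth:
            kept_rows.append(row)
        else:
            kept_rows.append(rng.multivariate_hypergeometric(row, depth))
        kept_ids.append(sid)
    if not kept_ids:
        raise ValueError(f"every sample is below the rarefaction depth {depth}")
    df = pd.DataFrame(
        np.asarray(kept_rows), index=kept_ids, columns=table.feature_ids
    )
    return FeatureTable(df)


def shannon(counts, base: float = 2.0) -> float:
    """Shannon diversity ``-sum p_i log_base p_i`` over positive entries."""
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise ValueError("Shannon diversity undefined for an all-zero sample")
    p = c[c > 0] / c.sum()
    return float(-(p * (np.log(p) / np.log(base))).sum())


def observed_features(counts) -> int:
    """Number of features with a strictly positive count."""
    return int((np.asarray(counts) > 0).sum())


def alpha_table(table: FeatureTable, base: float = 2.0) -> pd.DataFrame:
    """Per-sample Shannon index and observed-feature richness."""
    return pd.DataFrame(
        {
            "shannon": [shannon(table.counts.loc[s], base=base) for s in table.sample_ids],
            "observed": [observed_features(table.counts.loc[s]) for s in table.sample_ids],
        },
        index=pd.Index(table.sample_ids, name="sample_id"),
    )


def _branch_masses(tree: TreeNode, prop: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch (length, descendant mass) via one post-order pass."""
    lengths = []
    masses = []
    stack: dict[int, float] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            m = float(prop.get(node.name, 0.0))
        else:
            m = sum(stack.pop(id(c)) for c in node.children)
        stack[id(node)] = m
        if node.parent is not None:  # the root has no branch above it
            lengths.append(node.length or 0.0)
            masses.append(m)
    return np.asarray(lengths), np.asarray(masses)


def _check_leaves(tree: TreeNode, prop: pd.Series, label: str) -> None:
    leaves = {t.name for t in tree.tips()}
    extra = [f for f, v in prop.items() if v > 0 and f not in leaves]
    if extra:
        raise ValueError(
            f"feature(s) with nonzero abundance absent from the tree ({label}): {extra}"
        )


def weighted_unifrac(tree: TreeNode, prop_a: pd.Series, prop_b: pd.Series) -> float:
    """Unnormalized weighted UniFrac between two relative-abundance vectors.

    ``sum over branches of l_b * |P_A(b) - P_B(b)|`` where ``P(b)`` is the
    proportion of the community descending from branch ``b``.  Features
    missing from a vector count as 0; a feature with positive abundance that
    is not a tree leaf is an error.
    """
    prop_a = pd.Series(prop_a, dtype=float)
    prop_b = pd.Series(prop_b, dtype=float)
    _check_leaves(tree, prop_a, "sample A")
    _check_leaves(tree, prop_b, "sample B")
    la, ma = _branch_masses(tree, prop_a)
    _, mb = _branch_masses(tree, prop_b)
    return float(np.sum(la * np.abs(ma - mb)))


def unifrac_matrix(tree: TreeNode, table: FeatureTable) -> DistanceMatrix:
    """Pairwise unnormalized weighted UniFrac over a (rarefied) table.

    Equivalent to elementwise :func:`weighted_unifrac` calls but computed
    from a single branch x sample mass matrix.
    """
    props = table.relative_abundance()
    _check_leaves(tree, props.sum(axis=0), "table")
    lengths = []
    mass_rows = []
    stack: dict[int, np.ndarray] = {}
    prop_arr = props.to_numpy()  # samples x features
    col = {f: i for i, f in enumerate(props.columns)}
    n = table.n_samples
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            i = col.get(node.name)
            m = prop_arr[:, i].copy() if i is not None else np.zeros(n)
        else:
            m = np.sum([stack.pop(id(c)) for c in node.children], axis=0)
        stack[id(node)] = m
        if node.parent is not None:
            lengths.append(node.length or 0.0)
            mass_rows.append(m)
    L = np.asarray(lengths)
    M = np.asarray(mass_rows)  # branches x samples
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(M[:, i, None] - M[:, i + 1:])
        D[i, i + 1:] = L @ diff
    D = D + D.T
    return DistanceMatrix(D, ids=table.sample_ids)


@dataclass(frozen=True)
class Ordination:
    """PCoA result: sample coordinates on axes ordered by eigenvalue."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    proportion_explained: np.ndarray  # per retained axis


def pcoa(D: DistanceMatrix, k: int = 2) -> Ordination:
    """Classical MDS: Gower-center ``-0.5 * C D^2 C``, eigendecompose, and
    scale eigenvectors by sqrt(eigenvalue) on the positive axes.

    Proportion explained is relative to the sum of positive eigenvalues.
    If fewer than ``k`` positive eigenvalues exist, fewer axes are returned
    with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = D.data
    n = d.shape[0]
    d2 = d ** 2
    c = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * c @ d2 @ c
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-12 if n else 0.0
    n_pos = int((evals > tol).sum())
    n_axes = min(k, n_pos)
    if n_axes < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalue(s); returning {n_axes} axes",
            stacklevel=2,
        )
    coords = evecs[:, :n_axes] * np.sqrt(evals[:n_axes])
    pos_sum = evals[:n_pos].sum()
    prop = evals[:n_axes] / pos_sum if pos_sum > 0 else np.zeros(n_axes)
    df = pd.DataFrame(
        coords,
        index=pd.Index(list(D.ids), name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(n_axes)],
    )
    return Ordination(coordinates=df, eigenvalues=evals, proportion_explained=prop)


def distances_to_group(
    D: DistanceMatrix,
    query_samples: list[str],
    reference_samples: list[str],
) -> pd.Series:
    """Mean distance from each query sample to the reference set (the query
    itself is excluded from the reference when present)."""
    if not reference_samples:
        raise ValueError("reference sample set is empty")
    df = D.to_data_frame()
    out = {}
    for q in query_samples:
        refs = [r for r in reference_samples if r != q]
        if not refs:
            raise ValueError(f"no reference samples left for query {q!r}")
        out[q] = float(df.loc[q, refs].mean())
    return pd.Series(out, name="distance_to_reference")
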