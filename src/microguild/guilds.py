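"""Co-abundance guild discovery.

The algorithm: keep prevalent ASVs (present in >= 25% of samples by
default), compute pairwise repeated-measures (within-subject) correlations
of their log10 relative abundances, convert to a correlation distance
``1 - r``, Ward-cluster the ASVs, and walk the dendrogram from the root,
splitting a node into its two clades only when a PERMANOVA on the node's
distance submatrix (labels = left/right clade) is significant at ``alpha``
(default 0.001, 9999 permutations).  Leaf sets that the test declines to
split are the guilds.

PERMANOVA here is the classical pseudo-F partition of squared distances
with label permutation as a multiset; when the number of distinct
labelings is small enough it is enumerated exactly (raw-fraction p),
otherwise permutations are sampled with the +1-corrected estimator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix
from sympy.utilities.iterables import multiset_permutations

from .io import FeatureTable

__all__ = [
    "Dendrogram",
    "GuildMap",
    "PermanovaResult",
    "prevalence_filter",
    "rm_correlation",
    "log_relative_abundance",
    "correlation_distance_matrix",
    "ward_linkage",
    "permanova",
    "split_guilds",
    "guild_abundance",
]

DEFAULT_PSEUDOCOUNT = 1e-6


# ---------------------------------------------------------------------------
# prevalence filtering

def prevalence_filter(
    table: FeatureTable,
    min_prevalence: float = 0.25,
    inclusive: bool = True,
) -> tuple[FeatureTable, float]:
    """Keep ASVs present (count > 0) in at least (``inclusive``) or more
    than ``min_prevalence`` of the samples.

    Returns the filtered table and the fraction of total reads retained.
    """
    if not 0 < min_prevalence < 1:
        raise ValueError("min_prevalence must be in (0, 1)")
    presence = (table.counts > 0).mean(axis=0)
    keep = presence >= min_prevalence if inclusive else presence > min_prevalence
    kept = list(table.counts.columns[keep])
    if not kept:
        raise ValueError(
            f"no ASV passes the {min_prevalence:.0%} prevalence filter; "
            "lower the threshold"
        )
    coverage = float(table.counts.loc[:, kept].to_numpy().sum()
                     / table.counts.to_numpy().sum())
    return FeatureTable(table.counts.loc[:, kept]), coverage


# ---------------------------------------------------------------------------
# repeated-measures correlation

def rm_correlation(x, y, subjects=None, degenerate_value: float = 0.0) -> float:
    """Within-subject (repeated-measures) correlation of two variables.

    Each subject's mean is subtracted from its own observations of ``x``
    and of ``y``; the centered values are pooled and the ordinary Pearson
    correlation is returned.  With a single subject (or ``subjects=None``)
    this reduces to plain Pearson.  When either centered variable has zero
    variance the correlation is undefined: ``degenerate_value`` is returned
    and a warning is emitted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 2:
        raise ValueError("need at least 2 paired observations")
    if subjects is None:
        subjects = np.zeros(x.size, dtype=int)
    subjects = np.asarray(subjects)
    if subjects.shape != x.shape:
        raise ValueError("subjects must label every observation")
    xc = np.empty_like(x)
    yc = np.empty_like(y)
    for s in np.unique(subjects):
        m = subjects == s
        xc[m] = x[m] - x[m].mean()
        yc[m] = y[m] - y[m].mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx <= 0 or vy <= 0:
        warnings.warn(
            "zero within-subject variance; repeated-measures correlation "
            f"undefined, returning {degenerate_value}",
            stacklevel=2,
        )
        return float(degenerate_value)
    return float((xc @ yc) / math.sqrt(vx * vy))


def log_relative_abundance(
    table: FeatureTable, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """log10(relative abundance + pseudocount), the correlation input."""
    return np.log10(table.relative_abundance() + pseudocount)


def correlation_distance_matrix(
    log_abund: pd.DataFrame,
    subjects=None,
) -> tuple[DistanceMatrix, list[tuple[str, str]]]:
    """All-pairs repeated-measures correlation distance ``1 - r`` over ASVs.

    ``log_abund`` is samples x ASVs (typically from
    :func:`log_relative_abundance`); ``subjects`` labels the samples (one
    subject id per row; None = every sample its own subject is NOT implied,
    None means a single pooled subject i.e. plain Pearson).

    Returns the ASV x ASV distance matrix (entries in [0, 2], zero
    diagonal) and the list of ASV pairs whose correlation was degenerate
    (zero centered variance; distance set to 1).
    """
    if log_abund.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    X = log_abund.to_numpy(dtype=float)
    n, p = X.shape
    if subjects is None:
        subj = np.zeros(n, dtype=int)
    else:
        subj = np.asarray(subjects)
    Xc = X.copy()
    for s in np.unique(subj):
        m = subj == s
        Xc[m] -= Xc[m].mean(axis=0)
    ss = (Xc ** 2).sum(axis=0)
    degenerate_cols = ss <= 0
    denom = np.sqrt(np.outer(ss, ss))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc.T @ Xc) / denom
    corr = np.clip(corr, -1.0, 1.0)
    ids = list(log_abund.columns)
    deg_pairs: list[tuple[str, str]] = []
    if degenerate_cols.any():
        bad = np.where(degenerate_cols)[0]
        for i in bad:
            for j in range(p):
                if j != i:
                    corr[i, j] = 0.0
                    corr[j, i] = 0.0
                    pair = (ids[min(i, j)], ids[max(i, j)])
                    if pair not in deg_pairs:
                        deg_pairs.append(pair)
        warnings.warn(
            f"{len(bad)} ASV(s) with zero centered variance; their "
            "correlations were set to the degenerate value 0",
            stacklevel=2,
        )
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, 2.0)
    return DistanceMatrix(d, ids=ids), deg_pairs


# ---------------------------------------------------------------------------
# Ward clustering

@dataclass(frozen=True)
class Dendrogram:
    """Binary merge tree over ASVs (scipy linkage encoding)."""

    ids: list[str]
    linkage_matrix: np.ndarray  # scipy (n-1) x 4

    def __post_init__(self) -> None:
        heights = self.linkage_matrix[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def root(self):
        return to_tree(self.linkage_matrix)


def ward_linkage(D: DistanceMatrix) -> Dendrogram:
    """Agglomerative clustering with Ward's minimum-variance criterion
    (Lance-Williams updates on squared input distances, i.e. the "ward.D2"
    convention).  Deterministic: scipy's nearest-neighbor chain with
    lowest-index tie-breaking."""
    if len(D.ids) < 2:
        raise ValueError("need at least 2 objects to cluster")
    if not np.all(np.isfinite(D.data)):
        raise ValueError("non-finite distances")
    Z = linkage(squareform(D.data, checks=False), method="ward")
    return Dendrogram(ids=list(D.ids), linkage_matrix=Z)


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int  # permutations/labelings actually evaluated (excl. observed)
    exact: bool

    def __post_init__(self) -> None:
        if not (0 <= self.r2 <= 1 + 1e-12):
            raise ValueError(f"R^2 out of range: {self.r2}")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p-value out of range: {self.p_value}")


def _ss_parts(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in uniq:
        m = labels == g
        ng = int(m.sum())
        ss_within += d2[np.ix_(m, m)].sum() / (2 * ng)
    return ss_total, ss_within


def _pseudo_f(ss_total: float, ss_within: float, n: int, a: int) -> float:
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return math.inf
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def _n_distinct_labelings(counts: np.ndarray) -> int:
    total = math.factorial(int(counts.sum()))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def permanova(
    D: DistanceMatrix,
    labels,
    n_perm: int = 9999,
    seed: int | None = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``SS_total = (1/N) sum_{i<j} d_ij^2``; ``SS_within`` sums the analogous
    per-group terms; ``pseudo-F = (SS_between/(a-1)) / (SS_within/(N-a))``.
    Labels are permuted as a multiset.  When the number of distinct
    labelings is <= ``n_perm`` they are enumerated exhaustively and the
    p-value is the raw fraction of labelings with ``F >= F_observed``;
    otherwise ``n_perm`` random permutations are drawn and the
    +1-corrected estimator is used.
    """
    labels = np.asarray(labels)
    d = D.data
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValueError("one label per object required")
    uniq, inv = np.unique(labels, return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    counts = np.bincount(inv)
    if n - a < 1:
        raise ValueError("residual degrees of freedom < 1")
    d2 = d ** 2
    ss_total, ss_within = _ss_parts(d2, inv, np.arange(a))
    f_obs = _pseudo_f(ss_total, ss_within, n, a)
    r2 = 0.0 if ss_total <= 0 else (ss_total - ss_within) / ss_total
    r2 = min(max(r2, 0.0), 1.0)

    n_distinct = _n_distinct_labelings(counts)
    # tolerance so that analytically-tied F values (e.g. all-equal
    # distances) compare as ties despite float rounding
    tol = 1e-12 * max(1.0, abs(f_obs) if math.isfinite(f_obs) else 1.0)

    if n_distinct <= n_perm:
        hits = 0
        total = 0
        for perm in multiset_permutations(list(inv)):
            lab = np.asarray(perm)
            _, ssw = _ss_parts(d2, lab, np.arange(a))
            f = _pseudo_f(ss_total, ssw, n, a)
            if f >= f_obs - tol:
                hits += 1
            total += 1
        return PermanovaResult(
            pseudo_f=f_obs, r2=r2, p_value=hits / total,
            n_permutations=total, exact=True,
        )

    rng = np.random.default_rng(seed)
    # vectorized: per permutation, SS_within = sum_g (1/2 n_g) b_g' D2 b_g
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    lab_perm = inv[perms]  # n_perm x n
    ssw = np.zeros(n_perm)
    for g in range(a):
        B = (lab_perm == g).astype(float)
        ssw += np.einsum("ij,ij->i", B @ d2, B) / (2 * counts[g])
    ssb = ss_total - ssw
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ssb / (a - 1)) / (ssw / (n - a))
    f_perm = np.where(ssw <= 0, np.inf, f_perm)
    hits = int(np.sum(f_perm >= f_obs - tol))
    p = (hits + 1) / (n_perm + 1)
    return PermanovaResult(
        pseudo_f=f_obs, r2=r2, p_value=p, n_permutations=n_perm, exact=False,
    )


# ---------------------------------------------------------------------------
# recursive dendrogram splitting

@dataclass(frozen=True)
class GuildMap:
    """Partition of the prevalent ASVs into guilds, with the decision log
    of every PERMANOVA gate visited."""

    guilds: dict[int, tuple[str, ...]]  # guild id -> member ASVs
    decision_log: pd.DataFrame
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for members in self.guilds.values():
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"guilds overlap on: {sorted(overlap)}")
            seen |= set(members)

    @property
    def n_guilds(self) -> int:
        return len(self.guilds)

    def members(self) -> set[str]:
        return {m for ms in self.guilds.values() for m in ms}

    def labels(self) -> pd.Series:
        """ASV -> guild id, in guild order."""
        out = {}
        for gid, members in self.guilds.items():
            for m in members:
                out[m] = gid
        return pd.Series(out, name="guild")


def split_guilds(
    dend: Dendrogram,
    D: DistanceMatrix,
    alpha: float = 0.001,
    n_perm: int = 9999,
    seed: int = 0,
    min_leaves_to_test: int = 3,
) -> GuildMap:
    """Recursively cut the Ward dendrogram into guilds with PERMANOVA gates.

    Depth-first from the root: at each internal node with at least
    ``min_leaves_to_test`` leaves, PERMANOVA compares the left and right
    clades on the node's distance submatrix; if ``p < alpha`` both children
    are visited, otherwise the node's leaf set becomes a guild.  Nodes too
    small to test become guilds untested.  Guild ids follow dendrogram
    (left-to-right leaf) order.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if set(dend.ids) != set(D.ids):
        raise ValueError("dendrogram and distance matrix ids differ")
    pos = {name: D.ids.index(name) for name in dend.ids}
    d_full = D.data
    root = dend.root()

    guilds: dict[int, tuple[str, ...]] = {}
    log_rows: list[dict] = []
    seed_seq = np.random.SeedSequence(seed)
    counter = {"node": 0, "guild": 0}

    def leaf_names(node) -> list[str]:
        return [dend.ids[i] for i in node.pre_order(lambda x: x.id) if i < dend.n_leaves]

    def emit_guild(names: list[str]) -> None:
        counter["guild"] += 1
        guilds[counter["guild"]] = tuple(names)

    def visit(node) -> None:
        if node.is_leaf():
            emit_guild([dend.ids[node.id]])
            return
        left = leaf_names(node.get_left())
        right = leaf_names(node.get_right())
        names = left + right
        counter["node"] += 1
        node_id = counter["node"]
        if len(names) < min_leaves_to_test:
            emit_guild(names)
            log_rows.append({
                "node": node_id, "n_left": len(left), "n_right": len(right),
                "pseudo_f": np.nan, "r2": np.nan, "p_value": np.nan,
                "exact": False, "tested": False, "split": False,
            })
            return
        idx = [pos[nm] for nm in names]
        sub = DistanceMatrix(d_full[np.ix_(idx, idx)], ids=names)
        labels = np.array([0] * len(left) + [1] * len(right))
        node_seed = int(seed_seq.entropy % (2 ** 31)) ^ (node_id * 2654435761 % (2 ** 31))
        res = permanova(sub, labels, n_perm=n_perm, seed=node_seed)
        split = res.p_value < alpha
        log_rows.append({
            "node": node_id, "n_left": len(left), "n_right": len(right),
            "pseudo_f": res.pseudo_f, "r2": res.r2, "p_value": res.p_value,
            "exact": res.exact, "tested": True, "split": split,
        })
        if split:
            visit(node.get_left())
            visit(node.get_right())
        else:
            emit_guild(names)

    visit(root)
    log = pd.DataFrame(
        log_rows,
        columns=["node", "n_left", "n_right", "pseudo_f", "r2", "p_value",
                 "exact", "tested", "split"],
    )
    gm = GuildMap(
        guilds=guilds,
        decision_log=log,
        params={
            "alpha": alpha, "n_perm": n_perm, "seed": seed,
            "min_leaves_to_test": min_leaves_to_test,
        },
    )
    if gm.members() != set(dend.ids):
        raise AssertionError("guilds do not partition the ASV set")
    return gm


# ---------------------------------------------------------------------------
# guild abundance

def guild_abundance(rel_abund: pd.DataFrame, guilds: GuildMap) -> pd.DataFrame:
    """Sum member relative abundances per guild (samples x guilds).

    ``rel_abund`` is samples x ASVs relative abundances of the FULL table,
    so each guild's abundance is its share of the whole community.
    """
    out = {}
    for gid, members in guilds.guilds.items():
        missing = [m for m in members if m not in rel_abund.columns]
        if missing:
            raise KeyError(f"guild {gid} member(s) missing from table: {missing}")
        out[f"guild{gid}"] = rel_abund.loc[:, list(members)].sum(axis=1)
    return pd.DataFrame(out, index=rel_abund.index)
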