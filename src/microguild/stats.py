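"""Group-comparison statistics: Kruskal-Wallis with Dunn's post hoc and a
compact letter display, Mann-Whitney, Wilcoxon matched-pairs, Spearman.

All tests are two-sided.  Dunn's pairwise p-values are Bonferroni-adjusted
over the pairs tested by default (the GraphPad-style convention); Holm and
no adjustment are available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairwiseTestTable",
    "kruskal_wallis",
    "dunn_posthoc",
    "compact_letters",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "spearman",
]


@dataclass(frozen=True)
class PairwiseTestTable:
    """Pairwise statistics with raw and multiplicity-adjusted p-values."""

    table: pd.DataFrame  # columns: group_a, group_b, statistic, p_raw, p_adj
    adjustment: str

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.table["group_a"], self.table["group_b"]))

    def adjusted_p(self, a: str, b: str) -> float:
        t = self.table
        m = ((t.group_a == a) & (t.group_b == b)) | ((t.group_a == b) & (t.group_b == a))
        if not m.any():
            raise KeyError(f"no pair ({a}, {b}) in table")
        return float(t.loc[m, "p_adj"].iloc[0])


def _group_arrays(values, groups) -> dict:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    return {g: values[groups == g] for g in pd.unique(groups)}


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (a-1 df).

    All-identical values give H = 0, p = 1 by convention.
    """
    by_group = _group_arrays(values, groups)
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups")
    flat = np.concatenate(list(by_group.values()))
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*by_group.values())
    return float(h), float(p)


def dunn_posthoc(values, groups, adjust: str = "bonferroni") -> PairwiseTestTable:
    """Dunn's rank-sum post hoc for all group pairs.

    ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))`` with
    the tie term ``T = sum(t^3 - t) / (12 (N - 1))``; two-sided normal p.
    """
    if adjust not in ("none", "bonferroni", "holm"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    by_group = _group_arrays(values, groups)
    names = list(by_group.keys())
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    flat = np.concatenate([by_group[g] for g in names])
    labels = np.concatenate([[g] * len(by_group[g]) for g in names])
    n_total = len(flat)
    ranks = sps.rankdata(flat)
    mean_rank = {g: ranks[labels == g].mean() for g in names}
    n = {g: int((labels == g).sum()) for g in names}
    _, tie_counts = np.unique(flat, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12 - tie_term

    rows = []
    for a, b in combinations(names, 2):
        var = base_var * (1 / n[a] + 1 / n[b])
        if var <= 0:
            rows.append({"group_a": a, "group_b": b, "statistic": 0.0,
                         "p_raw": 1.0, "degenerate": True})
            continue
        z = (mean_rank[a] - mean_rank[b]) / math.sqrt(var)
        p = 2 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "statistic": float(z),
                     "p_raw": min(float(p), 1.0), "degenerate": False})
    df = pd.DataFrame(rows)
    df["p_adj"] = _adjust_p(df["p_raw"].to_numpy(), adjust)
    return PairwiseTestTable(table=df, adjustment=adjust)


def _adjust_p(p: np.ndarray, method: str) -> np.ndarray:
    m = len(p)
    if method == "none" or m == 0:
        return np.clip(p, 0, 1)
    if method == "bonferroni":
        return np.minimum(1.0, p * m)
    # holm step-down
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def compact_letters(pairs: PairwiseTestTable, alpha: float = 0.05,
                    groups: list | None = None) -> dict:
    """Insert-and-absorb compact letter display.

    Two groups share at least one letter iff their adjusted p >= alpha.
    Deterministic given the group order (default: order of appearance in
    the pairwise table).
    """
    if groups is None:
        seen: list = []
        for a, b in pairs.pairs():
            for g in (a, b):
                if g not in seen:
                    seen.append(g)
        groups = seen
    sig = {}
    for _, row in pairs.table.iterrows():
        key = frozenset((row["group_a"], row["group_b"]))
        sig[key] = row["p_adj"] < alpha

    columns: list[set] = [set(groups)]
    for a, b in combinations(groups, 2):
        if not sig.get(frozenset((a, b)), False):
            continue
        nxt: list[set] = []
        for col in columns:
            if a in col and b in col:
                nxt.extend([col - {b}, col - {a}])
            else:
                nxt.append(col)
        # absorb: drop empty/duplicate columns and any column contained
        # in another
        columns = []
        for col in nxt:
            if col and col not in columns and not any(
                col < other for other in nxt if other is not col
            ):
                columns.append(col)

    letters = "abcdefghijklmnopqrstuvwxyz"
    # order columns by first member's position for deterministic labels
    columns.sort(key=lambda col: min(groups.index(g) for g in col))
    out = {g: "" for g in groups}
    for i, col in enumerate(columns):
        for g in groups:
            if g in col:
                out[g] += letters[i % len(letters)]
    return out


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.  Exact null when both samples have
    n <= 8 and no ties; otherwise normal approximation with tie
    correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    no_ties = len(np.unique(np.concatenate([x, y]))) == x.size + y.size
    method = "exact" if (no_ties and x.size <= 8 and y.size <= 8) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon matched-pairs signed-ranks test.

    All-zero differences leave the statistic undefined: returns W=0, p=1
    with a warning.  Exact null for n <= 25 without ties/zeros."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diff = x - y
    if np.all(diff == 0):
        warnings.warn("all paired differences are zero; Wilcoxon undefined, p=1",
                      stacklevel=2)
        return 0.0, 1.0
    nz = diff[diff != 0]
    no_ties = len(np.unique(np.abs(nz))) == nz.size
    method = "exact" if (no_ties and nz.size <= 25) else "approx"
    res = sps.wilcoxon(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho (Pearson on ranks) with t-approximation p."""
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
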