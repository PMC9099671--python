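"""Synthetic 16S count-table generator with planted guild structure.

Emulates a 3-genotype x 6-mice x 2-timepoint fecal 16S study: guilds of
co-abundant ASVs share a latent log-abundance that carries genotype,
timepoint, mouse, and sample effects; noise ASVs are rare and zero-inflated
so a prevalence filter has true positives and negatives by construction;
reads are multinomial at a fixed sequencing depth; body weight is a linear
function of the relative abundance of a small causal guild set.

The latent model, per sample ``s`` and guild ``g``::

    lambda[g, s] = mu[g] + gamma[g, group(s)] + delta[g, time(s)]
                   + u[g, mouse(s)] + eps[g, s]

with ``u ~ N(0, sigma_mouse^2)`` and ``eps ~ N(0, sigma_sample^2)``; member
ASV ``i`` of guild ``g`` then has ``eta[i, s] = lambda[g, s] + a[i] +
e[i, s]`` with ``e ~ N(0, sigma_asv^2)``.  Per-sample proportions are the
softmax of ``eta`` over all ASVs (noise ASVs included, after zero-
inflation), and counts are ``Multinomial(depth, proportions)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import FeatureTable, SampleFrame

__all__ = ["SimParams", "SimTruth", "default_params", "paper_scale_params", "generate_dataset"]

_GROUP_NAMES_3 = ("WT", "IFABP-KO", "LFABP-KO")


def _default_gamma() -> np.ndarray:
    # guild x group genotype effects (natural-log scale).  The causal
    # guilds (2, 5, 7; 1-based) get pairwise linearly independent profiles
    # so each carries weight signal the others cannot proxy; amplitudes are
    # kept moderate so guild-specific sample noise contributes too.
    return np.array([
        [0.0, 0.0, 0.0],          # guild 1
        [-0.4, 0.0, 0.4],         # guild 2 (causal)
        [0.4, 0.0, -0.4],         # guild 3
        [0.0, -0.4, 0.4],         # guild 4
        [0.0, 0.4, -0.4],         # guild 5 (causal)
        [0.5, -0.5, 0.0],         # guild 6
        [0.4, -0.4, 0.0],         # guild 7 (causal)
        [-0.6, 0.6, 0.0],         # guild 8
    ])


def _default_delta() -> np.ndarray:
    # guild x timepoint diet-response effects; week 0 is the reference.
    shift = np.array([0.6, -0.4, 0.5, 0.0, -0.6, 0.4, 0.0, -0.5])
    return np.column_stack([np.zeros(8), shift])


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults are the documented study-scale scenario."""

    n_groups: int = 3
    mice_per_group: int = 6
    n_timepoints: int = 2
    n_guilds: int = 8
    members_per_guild: tuple[int, int] = (8, 8)  # inclusive range
    n_noise_asvs: int = 40
    depth: int = 17_000
    mu_guild: np.ndarray = field(default_factory=lambda: np.array([3.4, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0]))
    gamma: np.ndarray = field(default_factory=_default_gamma)
    delta: np.ndarray = field(default_factory=_default_delta)
    sigma_mouse: float = 0.3
    sigma_sample: float = 0.6
    sigma_asv: float = 0.3
    sigma_member: float = 0.5  # spread of per-ASV offsets a_i within a guild
    noise_mu: float = 0.0
    noise_sigma: float = 1.0
    noise_dropout: float = 0.92  # per-sample zero-inflation of noise ASVs
    beta0: float = 25.0  # grams, chow-fed adult mouse baseline
    group_weight_offsets: tuple[float, ...] = (0.0, -0.5, 0.5)
    timepoint_weight_offsets: tuple[float, ...] = (0.0, 10.0)  # HFD gain
    causal_guilds: tuple[int, ...] = (2, 5, 7)  # 1-based guild ids
    causal_betas: tuple[float, ...] = (70.0, -65.0, 60.0)
    sigma_weight: float = 0.5
    guild_coherent_tree: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_guilds < 1:
            raise ValueError("need at least one guild")
        if min(self.members_per_guild) < 1:
            raise ValueError("guilds must have at least one member")
        for s in (self.sigma_mouse, self.sigma_sample, self.sigma_asv,
                  self.sigma_member, self.sigma_weight, self.noise_sigma):
            if s < 0:
                raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.noise_dropout <= 1:
            raise ValueError("noise_dropout must be in [0, 1]")
        if not set(self.causal_guilds) <= set(range(1, self.n_guilds + 1)):
            raise ValueError("causal guild ids must lie in 1..n_guilds")
        if len(self.causal_betas) != len(self.causal_guilds):
            raise ValueError("one beta per causal guild required")
        for name in ("mu_guild",):
            if len(getattr(self, name)) != self.n_guilds:
                raise ValueError(f"{name} must have length n_guilds")
        if np.asarray(self.gamma).shape != (self.n_guilds, self.n_groups):
            raise ValueError("gamma must be n_guilds x n_groups")
        if np.asarray(self.delta).shape != (self.n_guilds, self.n_timepoints):
            raise ValueError("delta must be n_guilds x n_timepoints")

    @property
    def n_samples(self) -> int:
        return self.n_groups * self.mice_per_group * self.n_timepoints


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for recovery tests."""

    guild_of: dict[str, int | None]  # feature -> 1-based guild id; None = noise
    causal_guilds: tuple[int, ...]
    causal_betas: tuple[float, ...]
    latent_guild_proportions: pd.DataFrame  # samples x guilds (true proportions)
    seed: int

    def member_partition(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for asv, g in self.guild_of.items():
            if g is not None:
                out.setdefault(g, []).append(asv)
        return out

    def noise_features(self) -> list[str]:
        return [a for a, g in self.guild_of.items() if g is None]


def default_params(seed: int = 0) -> SimParams:
    """The study-scale scenario: 3 groups x 6 mice x 2 timepoints = 36
    samples; 8 guilds x 8 ASVs + 40 noise ASVs = 104 features; depth 17,000;
    causal guilds {2, 5, 7}."""
    return SimParams(seed=seed)


def paper_scale_params(seed: int = 0) -> SimParams:
    """A full-size scenario: 24 guilds x 8 ASVs + 600 zero-inflated noise
    ASVs = 792 features over 36 samples, mirroring the scale of a real
    36-sample fecal 16S table (~800 ASVs, ~200 prevalent)."""
    n_guilds = 24
    mu = np.full(n_guilds, 2.0)
    mu[0] = 3.4
    gamma = np.tile(_default_gamma(), (3, 1))
    delta = np.tile(_default_delta(), (3, 1))
    return SimParams(
        n_guilds=n_guilds,
        members_per_guild=(8, 8),
        n_noise_asvs=600,
        mu_guild=mu,
        gamma=gamma,
        delta=delta,
        seed=seed,
    )


def _group_names(n: int) -> list[str]:
    return list(_GROUP_NAMES_3) if n == 3 else [f"group{i + 1}" for i in range(n)]


def _timepoint_names(n: int) -> list[str]:
    return ["week0", "week11"] if n == 2 else [f"t{i}" for i in range(n)]


def _random_tree(names: Sequence[str], rng: np.random.Generator) -> TreeNode:
    """Random bifurcating topology by sequential pair-joining; exponential
    branch lengths (mean 0.1)."""
    nodes = [TreeNode(name=n, length=float(rng.exponential(0.1))) for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(0.1)), children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return root


def _guild_coherent_tree(
    partition: dict[int, list[str]], noise: list[str], rng: np.random.Generator
) -> TreeNode:
    clades = [_random_tree(m, rng) for m in partition.values()]
    if noise:
        clades.append(_random_tree(noise, rng))
    while len(clades) > 1:
        i, j = sorted(rng.choice(len(clades), size=2, replace=False))
        right = clades.pop(j)
        left = clades.pop(i)
        left.length = float(rng.exponential(0.1))
        right.length = float(rng.exponential(0.1))
        clades.append(TreeNode(children=[left, right]))
    root = clades[0]
    root.length = 0.0
    return root


def generate_dataset(
    params: SimParams | None = None,
) -> tuple[FeatureTable, SampleFrame, TreeNode, SimTruth]:
    """Draw one dataset (counts, metadata, tree, truth) from the model.

    Bit-reproducible for a given ``params`` (including its seed).
    """
    p = params if params is not None else default_params()
    rng = np.random.default_rng(p.seed)

    groups = _group_names(p.n_groups)
    times = _timepoint_names(p.n_timepoints)
    mice = [(g, m) for g in groups for m in range(1, p.mice_per_group + 1)]
    samples = [
        (f"{g}_m{m}_{t}", g, f"{g}_m{m}", t)
        for (g, m) in mice
        for t in times
    ]
    sample_ids = [s[0] for s in samples]
    group_idx = np.array([groups.index(s[1]) for s in samples])
    mouse_ids = [s[2] for s in samples]
    mouse_idx = np.array([[f"{g}_m{m}" for (g, m) in mice].index(mid) for mid in mouse_ids])
    time_idx = np.array([times.index(s[3]) for s in samples])
    n_s = len(samples)

    # guild memberships
    lo, hi = p.members_per_guild
    sizes = rng.integers(lo, hi + 1, size=p.n_guilds)
    guild_of: dict[str, int | None] = {}
    features: list[str] = []
    k = 0
    for g in range(p.n_guilds):
        for _ in range(sizes[g]):
            k += 1
            name = f"ASV{k:04d}"
            features.append(name)
            guild_of[name] = g + 1
    for _ in range(p.n_noise_asvs):
        k += 1
        name = f"ASV{k:04d}"
        features.append(name)
        guild_of[name] = None

    # latent guild abundances
    mu = np.asarray(p.mu_guild, dtype=float)
    u = rng.normal(0.0, p.sigma_mouse, size=(p.n_guilds, len(mice)))
    eps = rng.normal(0.0, p.sigma_sample, size=(p.n_guilds, n_s))
    lam = (
        mu[:, None]
        + np.asarray(p.gamma)[:, group_idx]
        + np.asarray(p.delta)[:, time_idx]
        + u[:, mouse_idx]
        + eps
    )  # guilds x samples

    # per-ASV log abundances
    n_members = int(sizes.sum())
    a = rng.normal(0.0, p.sigma_member, size=n_members)
    e = rng.normal(0.0, p.sigma_asv, size=(n_members, n_s))
    member_guild = np.concatenate([np.full(sizes[g], g) for g in range(p.n_guilds)])
    eta_members = lam[member_guild, :] + a[:, None] + e

    eta_noise = rng.normal(
        p.noise_mu, p.noise_sigma, size=(p.n_noise_asvs, n_s)
    )
    present = rng.random(size=(p.n_noise_asvs, n_s)) >= p.noise_dropout

    weights_members = np.exp(eta_members)
    weights_noise = np.exp(eta_noise) * present
    w = np.vstack([weights_members, weights_noise])  # features x samples
    props = w / w.sum(axis=0, keepdims=True)

    counts = np.empty((n_s, len(features)), dtype=np.int64)
    for s in range(n_s):
        counts[s] = rng.multinomial(p.depth, props[:, s])

    table = FeatureTable(pd.DataFrame(counts, index=sample_ids, columns=features))

    # true guild-level relative abundances (pre-sequencing proportions)
    guild_props = np.zeros((n_s, p.n_guilds))
    for g in range(p.n_guilds):
        guild_props[:, g] = props[: n_members][member_guild == g].sum(axis=0)
    latent = pd.DataFrame(
        guild_props,
        index=sample_ids,
        columns=[f"guild{g + 1}" for g in range(p.n_guilds)],
    )

    # body weight = baseline + group + timepoint + causal guild contributions
    weight = np.full(n_s, p.beta0)
    weight += np.asarray(p.group_weight_offsets)[group_idx]
    weight += np.asarray(p.timepoint_weight_offsets)[time_idx]
    for gid, beta in zip(p.causal_guilds, p.causal_betas):
        weight += beta * guild_props[:, gid - 1]
    weight += rng.normal(0.0, p.sigma_weight, size=n_s)

    meta = pd.DataFrame(
        {
            "subject_id": mouse_ids,
            "group": [s[1] for s in samples],
            "timepoint": [s[3] for s in samples],
            "cage_id": [f"cage_{g}_{(m - 1) // 3 + 1}" for (g, m) in
                        [(s[1], int(s[2].rsplit('m', 1)[1])) for s in samples]],
            "body_weight": np.round(weight, 3),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    frame = SampleFrame(meta)

    if p.guild_coherent_tree:
        partition = {g + 1: [f for f in features if guild_of[f] == g + 1]
                     for g in range(p.n_guilds)}
        noise = [f for f in features if guild_of[f] is None]
        tree = _guild_coherent_tree(partition, noise, rng)
    else:
        tree = _random_tree(features, rng)

    truth = SimTruth(
        guild_of=guild_of,
        causal_guilds=tuple(p.causal_guilds),
        causal_betas=tuple(p.causal_betas),
        latent_guild_proportions=latent,
        seed=p.seed,
    )
    return table, frame, tree, truth
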