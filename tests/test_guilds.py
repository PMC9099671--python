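import itertools
import math

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from microguild.guilds import (
    correlation_distance_matrix,
    guild_abundance,
    log_relative_abundance,
    permanova,
    prevalence_filter,
    rm_correlation,
    split_guilds,
    ward_linkage,
)
from microguild.io import FeatureTable


# ---------------------------------------------------------------------------
# independent PERMANOVA oracle: explicit loops, exhaustive enumeration

def _oracle_f(d, labels):
    n = len(labels)
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d[i, j] ** 2
    ss_total /= n
    ss_within = 0.0
    groups = sorted(set(labels))
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        s = 0.0
        for a_i, i in enumerate(idx):
            for j in idx[a_i + 1:]:
                s += d[i, j] ** 2
        ss_within += s / len(idx)
    a = len(groups)
    if ss_within <= 0:
        return math.inf, ss_total, ss_within
    f = ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))
    return f, ss_total, ss_within


def _oracle_exact_p(d, labels):
    f_obs, *_ = _oracle_f(d, labels)
    seen = set()
    hits = total = 0
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        f, *_ = _oracle_f(d, list(perm))
        tol = 1e-12 * max(1.0, abs(f_obs) if math.isfinite(f_obs) else 1.0)
        if f >= f_obs - tol:
            hits += 1
        total += 1
    return f_obs, hits / total


def _block_matrix(sizes, within, between):
    n = sum(sizes)
    d = np.full((n, n), between, dtype=float)
    start = 0
    for s in sizes:
        d[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(d, 0.0)
    return d


class TestPrevalenceFilter:
    def _table(self, presence_counts, n_samples=36):
        cols = {}
        for k, count in enumerate(presence_counts):
            col = np.zeros(n_samples, dtype=int)
            col[:count] = 5
            cols[f"f{k}"] = col
        cols["anchor"] = np.ones(n_samples, dtype=int)
        return FeatureTable(pd.DataFrame(cols))

    def test_present_in_10_of_36_retained(self):
        t = self._table([10])
        kept, _ = prevalence_filter(t, 0.25)
        assert "f0" in kept.feature_ids

    @pytest.mark.parametrize("inclusive,expected", [(True, True), (False, False)])
    def test_boundary_9_of_36(self, inclusive, expected):
        t = self._table([9])
        kept, _ = prevalence_filter(t, 0.25, inclusive=inclusive)
        assert ("f0" in kept.feature_ids) is expected

    def test_empty_result_advises(self):
        t = FeatureTable(pd.DataFrame(
            {"anchor": [1, 1, 1, 0], "rare": [0, 0, 0, 5]},
            index=["s1", "s2", "s3", "s4"]))
        with pytest.raises(ValueError, match="threshold"):
            prevalence_filter(t, 0.9)

    def test_synthetic_truth_separation(self, default_dataset):
        table, _, _, truth = default_dataset
        kept, coverage = prevalence_filter(table, 0.25)
        noise = set(truth.noise_features())
        assert not (set(kept.feature_ids) & noise)
        members = {m for ms in truth.member_partition().values() for m in ms}
        assert members <= set(kept.feature_ids)
        assert coverage > 0.9


class TestRmCorrelation:
    def test_single_subject_is_pearson(self):
        x = np.arange(5.0)
        assert rm_correlation(x, 2 * x + 1) == pytest.approx(1.0)

    def test_subject_centering_flips_pooled_sign(self):
        # within every mouse the two variables move oppositely even though
        # the pooled cloud is strongly positive
        x = np.array([1.0, 2.0, 10.0, 11.0])
        y = np.array([2.0, 1.0, 11.0, 10.0])
        subj = np.array(["S1", "S1", "S2", "S2"])
        assert rm_correlation(x, y, subj) == pytest.approx(-1.0)
        pooled = np.corrcoef(x, y)[0, 1]
        assert pooled > 0.9

    def test_constant_within_subject_flagged_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([5.0, 5.0, 7.0, 7.0])
        subj = np.array(["a", "a", "b", "b"])
        with pytest.warns(UserWarning, match="undefined"):
            assert rm_correlation(x, y, subj) == 0.0

    def test_matches_pingouin_rm_corr(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        n_subj, per = 6, 4
        subj = np.repeat(np.arange(n_subj), per)
        x = rng.normal(size=n_subj * per) + np.repeat(rng.normal(0, 3, n_subj), per)
        y = 0.5 * x + rng.normal(size=n_subj * per)
        df = pd.DataFrame({"x": x, "y": y, "s": subj})
        theirs = float(pingouin.rm_corr(df, x="x", y="y", subject="s")["r"].iloc[0])
        assert rm_correlation(x, y, subj) == pytest.approx(theirs, abs=1e-9)


class TestCorrelationDistance:
    def test_self_distance_zero_and_range(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(10, 5)), columns=list("abcde"))
        dm, deg = correlation_distance_matrix(df)
        assert not deg
        assert np.allclose(np.diag(dm.data), 0.0)
        assert dm.data.min() >= 0.0 and dm.data.max() <= 2.0

    def test_anticorrelated_pair_distance_two(self):
        x = np.arange(8.0)
        df = pd.DataFrame({"up": x, "down": -x})
        dm, _ = correlation_distance_matrix(df)
        assert dm["up", "down"] == pytest.approx(2.0)

    def test_guildmates_nearly_zero_without_asv_noise(self):
        import dataclasses

        import microguild as mg

        p = dataclasses.replace(mg.default_params(seed=2), sigma_asv=0.0)
        table, frame, _, truth = mg.generate_dataset(p)
        kept, _ = prevalence_filter(table, 0.25)
        la = log_relative_abundance(kept)
        subj = frame.subjects(kept.sample_ids).to_numpy()
        dm, _ = correlation_distance_matrix(la, subj)
        m = truth.member_partition()[2]
        assert dm[m[0], m[1]] < 0.1

    def test_degenerate_column_logged(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
        with pytest.warns(UserWarning, match="degenerate"):
            dm, deg = correlation_distance_matrix(df)
        assert ("a", "b") in deg
        assert dm["a", "b"] == pytest.approx(1.0)


class TestWardLinkage:
    def test_three_object_lance_williams(self):
        d = np.array([[0, 1, 5], [1, 0, 5], [5, 5, 0]], dtype=float)
        dend = ward_linkage(DistanceMatrix(d, ids=list("abc")))
        Z = dend.linkage_matrix
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(math.sqrt(33), abs=1e-9)

    def test_two_blocks_root_split(self):
        d = _block_matrix([4, 4], within=0.2, between=2.0)
        ids = [f"o{i}" for i in range(8)]
        dend = ward_linkage(DistanceMatrix(d, ids=ids))
        root = dend.root()
        left = {ids[i] for i in root.get_left().pre_order(lambda x: x.id)}
        assert left in ({"o0", "o1", "o2", "o3"}, {"o4", "o5", "o6", "o7"})

    def test_root_split_optimal_by_ward_objective(self):
        # exhaustive 2-partition check: the root bipartition minimizes the
        # Ward between-merge objective among all 2-partitions
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(0, 0.3, (4, 2)), rng.normal(3, 0.3, (3, 2))])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ids = [f"o{i}" for i in range(7)]
        dend = ward_linkage(DistanceMatrix(d, ids=ids))
        root = dend.root()
        left = frozenset(root.get_left().pre_order(lambda x: x.id))

        def ward_cost(groups):
            # within-cluster sum of squared distances / cluster size
            cost = 0.0
            for grp in groups:
                grp = list(grp)
                for a_i, i in enumerate(grp):
                    for j in grp[a_i + 1:]:
                        cost += d[i, j] ** 2 / len(grp)
            return cost

        best = min(
            (frozenset(c) for r in range(1, 4)
             for c in itertools.combinations(range(7), r)),
            key=lambda c: ward_cost([c, set(range(7)) - c]),
        )
        assert left in (best, frozenset(range(7)) - best)

    def test_heights_monotone(self, default_dataset):
        table, frame, _, _ = default_dataset
        kept, _ = prevalence_filter(table, 0.25)
        la = log_relative_abundance(kept)
        dm, _ = correlation_distance_matrix(
            la, frame.subjects(kept.sample_ids).to_numpy())
        dend = ward_linkage(dm)
        heights = dend.linkage_matrix[:, 2]
        assert np.all(np.diff(heights) >= -1e-9)

    def test_non_finite_rejected(self):
        d = np.array([[0.0, np.inf, 1.0], [np.inf, 0.0, 1.0], [1.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="finite"):
            ward_linkage(DistanceMatrix(d, ids=list("abc")))


class TestPermanova:
    def test_worked_example_two_plus_two(self):
        d = _block_matrix([2, 2], within=1.0, between=2.0)
        res = permanova(DistanceMatrix(d, ids=list("abcd")), ["g1", "g1", "g2", "g2"])
        assert res.pseudo_f == pytest.approx(7.0, abs=1e-12)
        assert res.r2 == pytest.approx(3.5 / 4.5, abs=1e-12)
        assert res.exact
        assert res.p_value == pytest.approx(1 / 3, abs=1e-15)

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        n_groups = int(rng.integers(2, 4))
        labels = [f"g{i % n_groups}" for i in range(n)]
        if len(set(labels)) < 2 or n - len(set(labels)) < 1:
            pytest.skip("degenerate draw")
        pts = rng.normal(size=(n, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = permanova(DistanceMatrix(d, ids=[str(i) for i in range(n)]), labels)
        f_oracle, p_oracle = _oracle_exact_p(d, labels)
        assert res.exact
        assert res.pseudo_f == pytest.approx(f_oracle, abs=1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-15)

    def test_all_equal_distances_p_one(self):
        d = _block_matrix([6], within=1.0, between=1.0)
        res = permanova(DistanceMatrix(d, ids=[str(i) for i in range(6)]),
                        ["a"] * 3 + ["b"] * 3)
        assert res.exact
        assert res.p_value == 1.0

    def test_zero_within_gives_infinite_f(self):
        d = _block_matrix([2, 2], within=0.0, between=1.0)
        res = permanova(DistanceMatrix(d, ids=list("abcd")), list("AABB"))
        assert math.isinf(res.pseudo_f)
        assert res.p_value <= 1.0

    def test_matches_skbio_statistic(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 3))
        pts[:6] += 1.5
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = DistanceMatrix(d, ids=[str(i) for i in range(12)])
        labels = ["x"] * 6 + ["y"] * 6
        ours = permanova(dm, labels, n_perm=99, seed=0)
        theirs = skbio_stats.permanova(dm, grouping=labels, permutations=99)
        assert ours.pseudo_f == pytest.approx(float(theirs["test statistic"]),
                                              abs=1e-10)

    def test_sampled_mode_plus_one_estimator(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(14, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = permanova(DistanceMatrix(d, ids=[str(i) for i in range(14)]),
                        ["a"] * 7 + ["b"] * 7, n_perm=999, seed=1)
        assert not res.exact
        assert res.p_value >= 1 / 1000

    def test_single_group_rejected(self):
        d = _block_matrix([4], within=1.0, between=1.0)
        with pytest.raises(ValueError, match="2 groups"):
            permanova(DistanceMatrix(d, ids=list("abcd")), ["g"] * 4)


class TestSplitGuilds:
    def _two_block_setup(self):
        d = _block_matrix([5, 5], within=0.1, between=1.0)
        ids = [f"a{i}" for i in range(10)]
        dm = DistanceMatrix(d, ids=ids)
        return ward_linkage(dm), dm, ids

    def test_two_blocks_split_at_permissive_alpha(self):
        dend, dm, ids = self._two_block_setup()
        gm = split_guilds(dend, dm, alpha=0.01, n_perm=9999, seed=0)
        assert gm.n_guilds == 2
        sets = {frozenset(v) for v in gm.guilds.values()}
        assert sets == {frozenset(ids[:5]), frozenset(ids[5:])}
        root_row = gm.decision_log.iloc[0]
        assert root_row["exact"] and root_row["p_value"] <= 1 / 126

    def test_strict_alpha_cannot_split_ten_leaves(self):
        # with 10 leaves the smallest enumerable p is 2/252 ~ 0.008, so the
        # study's alpha = 0.001 cannot split — documents why the gate needs
        # many ASVs
        dend, dm, ids = self._two_block_setup()
        gm = split_guilds(dend, dm, alpha=0.001, n_perm=9999, seed=0)
        assert gm.n_guilds == 1
        assert gm.decision_log.iloc[0]["tested"]

    def test_homogeneous_distances_single_guild(self):
        d = _block_matrix([8], within=0.7, between=0.7)
        ids = [f"a{i}" for i in range(8)]
        dm = DistanceMatrix(d, ids=ids)
        gm = split_guilds(ward_linkage(dm), dm, alpha=0.05, seed=0)
        assert gm.n_guilds == 1
        assert set(gm.guilds[1]) == set(ids)

    def test_partition_property(self, default_dataset):
        table, frame, _, _ = default_dataset
        kept, _ = prevalence_filter(table, 0.25)
        la = log_relative_abundance(kept)
        dm, _ = correlation_distance_matrix(
            la, frame.subjects(kept.sample_ids).to_numpy())
        dend = ward_linkage(dm)
        gm = split_guilds(dend, dm, seed=1)
        members = sorted(m for ms in gm.guilds.values() for m in ms)
        assert members == sorted(kept.feature_ids)
        assert gm.decision_log["tested"].any()

    def test_id_mismatch_rejected(self):
        dend, dm, ids = self._two_block_setup()
        other = DistanceMatrix(dm.data, ids=[f"b{i}" for i in range(10)])
        with pytest.raises(ValueError, match="ids differ"):
            split_guilds(dend, other)


class TestGuildAbundance:
    def test_single_guild_owning_everything_sums_to_one(self, small_table):
        from microguild.guilds import GuildMap

        gm = GuildMap(guilds={1: ("a", "b", "c")},
                      decision_log=pd.DataFrame(), params={})
        out = guild_abundance(small_table.relative_abundance(), gm)
        assert np.allclose(out["guild1"], 1.0)

    def test_missing_member_named(self, small_table):
        from microguild.guilds import GuildMap

        gm = GuildMap(guilds={1: ("a", "zzz")},
                      decision_log=pd.DataFrame(), params={})
        with pytest.raises(KeyError, match="zzz"):
            guild_abundance(small_table.relative_abundance(), gm)

    def test_tracks_latent_guild_signal(self, default_dataset):
        from scipy.stats import spearmanr

        from microguild.guilds import GuildMap

        table, _, _, truth = default_dataset
        gm = GuildMap(
            guilds={g: tuple(m) for g, m in truth.member_partition().items()},
            decision_log=pd.DataFrame(), params={},
        )
        out = guild_abundance(table.relative_abundance(), gm)
        for g in (1, 2, 5):
            rho = spearmanr(out[f"guild{g}"],
                            truth.latent_guild_proportions[f"guild{g}"]).statistic
            assert rho > 0.9
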