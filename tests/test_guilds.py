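import numpy as np
import pandas as pd
import pytest

from guildscan.datatypes import (
    CorrelationMatrix,
    DistanceMatrix,
    GuildAssignment,
    RelativeAbundanceTable,
    SampleMetadata,
)
from guildscan.guilds import (
    build_network,
    cut_tree_by_permanova,
    guild_abundance,
    guild_summary,
    permanova,
    to_distance,
    ward_linkage,
)
from helpers import (
    merge_leaf_sets,
    naive_ward_merges,
    permanova_exhaustive_p,
    permanova_f_direct,
)


def _random_distance(rng, n) -> DistanceMatrix:
    d = rng.random((n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix([f"x{i}" for i in range(n)], d)


def _block_distance(sizes, within=0.1, between=1.8) -> DistanceMatrix:
    labels = np.repeat(np.arange(len(sizes)), sizes)
    d = np.where(labels[:, None] == labels[None, :], within, between)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix([f"x{i}" for i in range(len(labels))], d)


class TestToDistance:
    @pytest.mark.parametrize("r,expected", [(1.0, 0.0), (-1.0, 2.0), (0.4, 0.6)])
    def test_one_minus_r(self, r, expected):
        corr = CorrelationMatrix(
            ["a", "b"], np.array([[1.0, r], [r, 1.0]])
        )
        d = to_distance(corr)
        assert d.d[0, 1] == pytest.approx(expected)
        assert d.d[0, 0] == 0.0


class TestWardLinkage:
    def test_two_items_base_case(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.8], [0.8, 0.0]]))
        tree = ward_linkage(dm)
        assert len(tree.merges) == 1
        assert tree.merges[0][2] == pytest.approx(0.8)

    def test_tight_blocks_separate_at_root(self):
        dm = _block_distance([4, 4])
        tree = ward_linkage(dm)
        left, right = tree.children(tree.root)
        sides = {frozenset(tree.leaf_names(left)), frozenset(tree.leaf_names(right))}
        assert sides == {
            frozenset(["x0", "x1", "x2", "x3"]),
            frozenset(["x4", "x5", "x6", "x7"]),
        }

    def test_merge_sequence_matches_naive_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 8))
            dm = _random_distance(rng, n)
            tree = ward_linkage(dm)
            mine = merge_leaf_sets(tree)
            oracle = naive_ward_merges(dm.d)
            for (ma, mb, mh), (oa, ob, oh) in zip(mine, oracle):
                assert {ma, mb} == {oa, ob}
                assert mh == pytest.approx(oh, abs=1e-9)

    def test_heights_match_scipy_ward(self, rng):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        dm = _random_distance(rng, 15)
        tree = ward_linkage(dm)
        Z = linkage(squareform(dm.d, checks=False), method="ward")
        np.testing.assert_allclose(
            sorted(m[2] for m in tree.merges), np.sort(Z[:, 2]), atol=1e-9
        )

    def test_ward_d_dialect_differs_on_heights(self, rng):
        dm = _random_distance(rng, 8)
        h2 = [m[2] for m in ward_linkage(dm, "ward.D2").merges]
        h1 = [m[2] for m in ward_linkage(dm, "ward.D").merges]
        assert not np.allclose(h1, h2)

    def test_single_item_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ward_linkage(DistanceMatrix(["a"], np.zeros((1, 1))))


class TestPermanova:
    def test_equal_distances_give_p_one(self):
        n = 8
        d = np.ones((n, n)) - np.eye(n)
        dm = DistanceMatrix([f"x{i}" for i in range(n)], d)
        res = permanova(dm, ["A"] * 4 + ["B"] * 4, n_perm=200, seed=0)
        assert res.p_value == 1.0

    def test_pseudo_f_matches_direct_formula(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 9))
            dm = _random_distance(rng, n)
            labels = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
            res = permanova(dm, labels, n_perm=9, seed=0)
            assert res.pseudo_F == pytest.approx(
                permanova_f_direct(dm.d, labels), abs=1e-12
            )

    def test_exact_p_equals_exhaustive_enumeration(self, rng):
        for _ in range(10):
            dm = _random_distance(rng, 6)
            labels = np.array(["A", "A", "A", "B", "B", "B"])
            res = permanova(dm, labels, method="exact")
            assert res.p_value == permanova_exhaustive_p(dm.d, labels)
            assert res.n_permutations == 19  # 20 distinct labelings - identity

    def test_three_group_exact_enumeration(self, rng):
        dm = _random_distance(rng, 6)
        labels = np.array(["A", "A", "B", "B", "C", "C"])
        res = permanova(dm, labels, method="exact")
        assert res.p_value == permanova_exhaustive_p(dm.d, labels)

    def test_minimum_p_bound(self, rng):
        # large enough groups that 999 random relabelings essentially never
        # reproduce the true partition, so p attains its floor of 1/1000
        dm = _block_distance([15, 15], within=0.01, between=1.9)
        res = permanova(dm, ["A"] * 15 + ["B"] * 15, n_perm=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_single_group_rejected(self, rng):
        dm = _random_distance(rng, 4)
        with pytest.raises(ValueError, match="2 groups"):
            permanova(dm, ["A"] * 4)


class TestCutTree:
    def test_exchangeable_distances_collapse_to_one_cag(self):
        n = 12
        d = 0.7 * (np.ones((n, n)) - np.eye(n))
        dm = DistanceMatrix([f"x{i}" for i in range(n)], d)
        tree = ward_linkage(dm)
        asg = cut_tree_by_permanova(tree, dm, alpha=0.001, n_perm=999, seed=0)
        assert asg.n_cags == 1

    @pytest.mark.parametrize("scope", ["tree", "node"])
    def test_planted_three_blocks_recovered_exactly(self, scope):
        dm = _block_distance([6, 7, 8])
        tree = ward_linkage(dm)
        asg = cut_tree_by_permanova(
            tree, dm, alpha=0.001, n_perm=999, seed=1, permutation_scope=scope
        )
        assert asg.n_cags == 3
        truth = {f"x{i}": f"G{g}" for g, size in enumerate([6, 7, 8])
                 for i in range(sum([6, 7, 8][:g]), sum([6, 7, 8][: g + 1]))}
        from guildscan.simulate import evaluate_recovery

        assert evaluate_recovery(asg, truth) == 1.0

    def test_maximally_significant_node_always_recurses(self):
        # with 999 permutations the smallest attainable p is 1/1000 = 0.001,
        # which is NOT > 0.001, so a perfectly separated root must split
        dm = _block_distance([6, 6], within=0.05, between=1.9)
        tree = ward_linkage(dm)
        asg = cut_tree_by_permanova(tree, dm, alpha=0.001, n_perm=999, seed=3)
        assert asg.n_cags >= 2

    def test_partition_properties_and_alpha_monotonicity(self, rng):
        dm = _random_distance(rng, 20)
        tree = ward_linkage(dm)
        previous = 0
        for alpha in (1e-9, 0.001, 0.5):
            asg = cut_tree_by_permanova(tree, dm, alpha=alpha, n_perm=199, seed=5)
            assert sorted(asg.mapping) == sorted(dm.ids)  # partition covers all
            assert asg.n_cags >= max(previous, 1)
            previous = asg.n_cags
        tiny = cut_tree_by_permanova(tree, dm, alpha=1e-9, n_perm=199, seed=5)
        assert tiny.n_cags == 1  # p >= 1/200 always exceeds alpha

    def test_invalid_alpha(self, rng):
        dm = _random_distance(rng, 5)
        tree = ward_linkage(dm)
        for alpha in (0.0, 1.0, -1, 2):
            with pytest.raises(ValueError, match="alpha"):
                cut_tree_by_permanova(tree, dm, alpha=alpha)


@pytest.fixture
def rel_table():
    return RelativeAbundanceTable(
        pd.DataFrame(
            [[0.1, 0.25, 0.3, 0.35], [0.2, 0.2, 0.25, 0.35]],
            index=["s1", "s2"],
            columns=["a", "b", "c", "d"],
        )
    )


class TestGuildAbundance:
    def test_single_cag_recovers_row_totals(self, rel_table):
        asg = GuildAssignment({x: "CAG1" for x in "abcd"})
        g = guild_abundance(rel_table, asg)
        np.testing.assert_allclose(g.df["CAG1"], rel_table.df.sum(axis=1))

    def test_additivity(self, rel_table):
        asg = GuildAssignment({"a": "CAG1", "b": "CAG1", "c": "CAG2", "d": "CAG2"})
        g = guild_abundance(rel_table, asg)
        assert g.df.loc["s1", "CAG1"] == pytest.approx(0.35)
        assert g.df.loc["s1", "CAG2"] == pytest.approx(0.65)

    def test_group_cv_zero_when_samples_identical(self, rel_table):
        rel = RelativeAbundanceTable(
            pd.DataFrame(
                [[0.4, 0.6], [0.4, 0.6]], index=["s1", "s2"], columns=["a", "b"]
            )
        )
        asg = GuildAssignment({"a": "CAG1", "b": "CAG2"})
        meta = SampleMetadata(
            pd.DataFrame(
                {"group": ["HF", "HF"], "timepoint": ["d0", "d0"]},
                index=["s1", "s2"],
            )
        )
        summary = guild_summary(guild_abundance(rel, asg), meta)
        assert (summary["cv"] == 0).all()


class TestBuildNetwork:
    def _corr(self, r01, r02=0.0, r12=0.0):
        m = np.array([[1.0, r01, r02], [r01, 1.0, r12], [r02, r12, 1.0]])
        return CorrelationMatrix(["a", "b", "c"], m)

    @pytest.fixture
    def rel3(self):
        return RelativeAbundanceTable(
            pd.DataFrame(
                [[0.2, 0.3, 0.5]], index=["s1"], columns=["a", "b", "c"]
            )
        )

    def test_below_threshold_edge_hidden(self, rel3):
        asg = GuildAssignment({"a": "CAG1", "b": "CAG1", "c": "CAG2"})
        net = build_network(self._corr(0.59), asg, rel3, min_abs_r=0.6)
        assert net.number_of_edges() == 0
        net = build_network(self._corr(0.60), asg, rel3, min_abs_r=0.6)
        assert net.has_edge("a", "b")

    def test_negative_edge_sign(self, rel3):
        asg = GuildAssignment({"a": "CAG1", "b": "CAG1", "c": "CAG2"})
        net = build_network(self._corr(-0.7), asg, rel3, min_abs_r=0.6)
        assert net.edges["a", "b"]["sign"] == "neg"
        assert net.nodes["a"]["mean_relative_abundance"] == pytest.approx(0.2)
        assert net.nodes["c"]["cag"] == "CAG2"

    def test_threshold_monotone_pruning(self, rng, rel3):
        asg = GuildAssignment({"a": "CAG1", "b": "CAG1", "c": "CAG2"})
        corr = self._corr(0.7, -0.65, 0.3)
        edges = [
            set(map(frozenset, build_network(corr, asg, rel3, min_abs_r=t).edges))
            for t in (0.2, 0.6, 0.69, 0.9)
        ]
        for smaller, larger in zip(edges[1:], edges[:-1]):
            assert smaller <= larger
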