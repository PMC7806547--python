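import itertools

import numpy as np
import pandas as pd
import pytest

from guildscan.community import (
    alpha_diversity,
    bray_curtis,
    groupwise_tests,
    pairwise_permanova,
    pcoa,
    observed_asvs,
    shannon,
)
from guildscan.datatypes import DistanceMatrix, FeatureTable, SampleMetadata
from guildscan.preprocess import rarefy, to_relative
from guildscan.stats import bh_adjust


class TestShannon:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([8, 8, 8, 8], 2.0),
            ([16, 0, 0, 0], 0.0),
            ([12, 4], -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))),
        ],
    )
    def test_values_in_bits(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected, abs=1e-9)

    def test_bounded_by_log_richness(self, rng):
        counts = rng.integers(0, 50, size=30)
        counts[0] += 1
        assert shannon(counts) <= np.log2(observed_asvs(counts)) + 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])

    def test_natural_log_base_option(self):
        assert shannon([8, 8], base=np.e) == pytest.approx(np.log(2))


class TestObservedAsvs:
    def test_counts_positive_entries(self):
        assert observed_asvs([8, 8, 8, 8]) == 4
        assert observed_asvs([0, 0]) == 0

    def test_rarefaction_never_increases_richness(self, rng):
        counts = rng.integers(0, 30, size=(4, 25))
        counts[:, 0] += 5
        table = FeatureTable(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(4)],
                         columns=[f"a{j}" for j in range(25)])
        )
        rarefied, _ = rarefy(table, 20, seed=0)
        for sid in rarefied.sample_ids:
            before = observed_asvs(table.df.loc[sid])
            after = observed_asvs(rarefied.df.loc[sid])
            assert after <= before


class TestBrayCurtis:
    def test_identical_and_disjoint_samples(self):
        t = FeatureTable(
            pd.DataFrame(
                [[5, 5, 0, 0], [5, 5, 0, 0], [0, 0, 3, 7]],
                index=["s1", "s2", "s3"], columns=list("abcd"),
            )
        )
        bc = bray_curtis(t)
        assert bc.d[0, 1] == pytest.approx(0.0)
        assert bc.d[0, 2] == pytest.approx(1.0)

    def test_direct_formula(self):
        t = FeatureTable(
            pd.DataFrame([[6, 2], [2, 6]], index=["u", "v"], columns=["a", "b"])
        )
        assert bray_curtis(t).d[0, 1] == pytest.approx(0.5)

    def test_equal_depth_counts_match_relative_abundance(self, rng):
        counts = rng.integers(0, 40, size=(5, 15)) + 1
        table = FeatureTable(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(5)],
                         columns=[f"a{j}" for j in range(15)])
        )
        rarefied, _ = rarefy(table, 100, seed=1)
        rel = to_relative(rarefied)
        np.testing.assert_allclose(
            bray_curtis(rarefied).d, bray_curtis(rel).d, atol=1e-12
        )


class TestPcoa:
    def test_equilateral_triangle(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(["a", "b", "c"], d))
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])
        coords = res.coordinates.to_numpy()
        for i, j in itertools.combinations(range(3), 2):
            assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(1.0)

    def test_collinear_points_recover_line(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        d = np.abs(x[:, None] - x[None, :])
        res = pcoa(DistanceMatrix(list("abcd"), d))
        assert np.sum(res.eigenvalues > 1e-8) == 1
        rec = np.abs(
            res.coordinates["PC1"].to_numpy()[:, None]
            - res.coordinates["PC1"].to_numpy()[None, :]
        )
        np.testing.assert_allclose(rec, d, atol=1e-9)

    def test_reconstructs_euclidean_embeddable_distances(self, rng):
        counts = rng.integers(0, 60, size=(6, 12)) + 1
        table = FeatureTable(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(6)],
                         columns=[f"a{j}" for j in range(12)])
        )
        bc = bray_curtis(table)
        res = pcoa(bc)
        if np.all(res.eigenvalues >= -1e-10):
            coords = res.coordinates.to_numpy()
            rec = np.sqrt(
                ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
            )
            np.testing.assert_allclose(rec, bc.d, atol=1e-8)

    def test_proportions_non_increasing_and_bounded(self, rng):
        d = rng.random((7, 7))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        res = pcoa(DistanceMatrix([f"x{i}" for i in range(7)], d))
        assert np.all(res.proportion_explained <= 1 + 1e-12)
        assert np.all(np.diff(res.proportion_explained) <= 1e-12)

    def test_agrees_with_skbio(self, rng):
        import warnings

        from skbio.stats.ordination import pcoa as skbio_pcoa

        counts = rng.integers(0, 60, size=(8, 10)) + 1
        table = FeatureTable(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(8)],
                         columns=[f"a{j}" for j in range(10)])
        )
        bc = bray_curtis(table)
        res = pcoa(bc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = skbio_pcoa(bc.d, method="eigh")
        n_pos = res.coordinates.shape[1]
        np.testing.assert_allclose(
            res.eigenvalues[:n_pos], ref.eigvals.to_numpy()[:n_pos], atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(res.coordinates.to_numpy()),
            np.abs(ref.samples.to_numpy()[:, :n_pos]),
            atol=1e-6,
        )


class TestGroupwiseTests:
    def _alpha_meta(self, values_by_group, timepoint="d0"):
        rows, meta = {}, {}
        i = 0
        for group, values in values_by_group.items():
            for v in values:
                sid = f"s{i}"
                rows[sid] = v
                meta[sid] = group
                i += 1
        alpha = pd.DataFrame(
            {"shannon": rows, "observed_asvs": {k: 1 for k in rows}}
        )
        metadata = SampleMetadata(
            pd.DataFrame(
                {
                    "group": pd.Series(meta),
                    "timepoint": timepoint,
                }
            )
        )
        return alpha, metadata

    def test_identical_groups_give_h_zero_p_one(self):
        alpha, meta = self._alpha_meta(
            {"A": [1, 2, 3], "B": [3, 1, 2], "C": [2, 3, 1]}
        )
        out = groupwise_tests(alpha, meta, metrics=("shannon",))
        assert out["H"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.0

    def test_extreme_separation_matches_exact_enumeration(self):
        # {1,2,3} vs {10,11,12}: of the 20 distinct labelings only the true
        # one and its mirror give maximal rank separation -> exact p = 0.1
        alpha, meta = self._alpha_meta({"A": [1, 2, 3], "B": [10, 11, 12]})
        out = groupwise_tests(alpha, meta, metrics=("shannon",))
        assert out["p"].iloc[0] == pytest.approx(2 / 20)

    def test_bh_within_metric_family(self):
        # four timepoints with known raw p ordering adjust monotonically
        rng = np.random.default_rng(0)
        frames, metas = [], []
        for t, shift in zip(["d0", "d7", "d77", "d84"], [0, 1, 2, 4]):
            a = rng.normal(0, 1, 12)
            b = rng.normal(shift, 1, 12)
            alpha, meta = self._alpha_meta({"A": a, "B": b}, timepoint=t)
            alpha.index = [f"{t}_{s}" for s in alpha.index]
            meta.df.index = [f"{t}_{s}" for s in meta.df.index]
            frames.append(alpha)
            metas.append(meta.df)
        alpha = pd.concat(frames)
        meta = SampleMetadata(pd.concat(metas))
        out = groupwise_tests(alpha, meta, metrics=("shannon",))
        order_raw = out.sort_values("p")["q"].to_numpy()
        assert np.all(np.diff(order_raw) >= -1e-12)
        np.testing.assert_allclose(
            out["q"].to_numpy(), bh_adjust(out["p"].to_numpy()), atol=1e-12
        )


class TestPairwisePermanova:
    def test_groups_compared_within_timepoint_with_bh(self, rng):
        # two timepoints, three groups; distances with real group structure
        # for only one timepoint
        ids, meta_rows, vecs = [], [], []
        for t, sep in (("d0", 0.0), ("d105", 3.0)):
            for g, shift in (("HF", 0.0), ("UP", sep), ("ARP", 2 * sep)):
                for m in range(5):
                    ids.append(f"{g}.{m}.{t}")
                    meta_rows.append({"group": g, "timepoint": t})
                    vecs.append(rng.normal(shift, 1.0, 4))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(np.array(vecs)))
        dm = DistanceMatrix(ids, d)
        meta = SampleMetadata(pd.DataFrame(meta_rows, index=ids))
        out = pairwise_permanova(dm, meta, n_perm=499, seed=0)
        assert len(out) == 6  # 3 pairs x 2 timepoints
        d105 = out[out["timepoint"] == "d105"]
        d0 = out[out["timepoint"] == "d0"]
        assert (d105["q"] < 0.05).all()
        assert (d0["q"] > 0.05).all()

    def test_agrees_with_skbio_permanova(self, rng):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.stats.distance import permanova as skbio_permanova

        from guildscan.guilds import permanova as my_permanova

        n = 12
        d = rng.random((n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        labels = ["A"] * 6 + ["B"] * 6
        ids = [f"x{i}" for i in range(n)]
        mine = my_permanova(DistanceMatrix(ids, d), labels, n_perm=999, seed=0)
        ref = skbio_permanova(SkbioDM(d, ids), list(labels))
        assert mine.pseudo_F == pytest.approx(ref["test statistic"], abs=1e-10)
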