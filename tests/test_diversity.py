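"""Diversity indices: Gower/Podani distances, MPD, cophenetic distances and
community means, checked against brute-force oracles and hand arithmetic."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import patchscape as ps
from conftest import random_trait_table
from oracles import cophenetic_brute, gower_pair, mpd_brute, tree_to_newick


def _table(values: dict, scales: dict, blocks=None):
    species = [f"s{i}" for i in range(len(next(iter(values.values()))))]
    vdf = pd.DataFrame(values, index=pd.Index(species, name="species_id"))
    meta = pd.DataFrame(
        {
            "block": [
                (blocks or {}).get(t, "vegetative") for t in values
            ],
            "scale": [scales[t] for t in values],
        },
        index=pd.Index(list(values), name="trait"),
    )
    return ps.TraitTable(vdf, meta)


class TestGower:
    def test_identical_rows_zero(self):
        t = _table({"a": [3.0, 3.0], "b": [1, 1]},
                   {"a": "continuous", "b": "binary"})
        d = ps.gower_block_distance(t)
        assert d.values[0, 1] == 0.0

    def test_single_continuous_range_normalised(self):
        t = _table({"a": [2.0, 7.0, 12.0]}, {"a": "continuous"})
        d = ps.gower_block_distance(t)
        assert d.values[0, 1] == pytest.approx(0.5)  # |2-7| / 10

    def test_mean_of_mixed_traits(self):
        t = _table({"a": [0, 1], "b": [5.0, 5.0]},
                   {"a": "binary", "b": "continuous"})
        d = ps.gower_block_distance(t)
        assert d.values[0, 1] == pytest.approx(0.5)  # mean(1, 0)

    def test_podani_hand_example_with_ties(self):
        # values (1, 2, 2, 4): ranks (1, 2.5, 2.5, 4); T(2) = 2
        t = _table({"o": [1, 2, 2, 4]}, {"o": "ordinal"})
        d = ps.gower_block_distance(t).values
        denom = 4 - 1  # r_max - r_min - 0 - 0
        assert d[0, 1] == pytest.approx((abs(1 - 2.5) - 0.5) / denom)
        assert d[1, 2] == 0.0  # equal values
        assert d[0, 3] == pytest.approx(1.0)  # the extremes
        assert d[1, 3] == pytest.approx((abs(2.5 - 4) - 0.5) / denom)

    def test_missing_pairwise_deletion(self):
        t = _table({"a": [0.0, 10.0, np.nan], "b": [0, 0, 1]},
                   {"a": "continuous", "b": "binary"})
        d = ps.gower_block_distance(t)
        assert d.values[0, 1] == pytest.approx(0.5)  # mean(1, 0)
        assert d.values[0, 2] == pytest.approx(1.0)  # only binary available
        assert not d.mask[0, 2]

    def test_all_missing_pair_masked(self):
        t = _table({"a": [1.0, np.nan]}, {"a": "continuous"})
        d = ps.gower_block_distance(t)
        assert d.mask[0, 1]

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 9))
            k = int(rng.integers(1, 5))
            table = random_trait_table(rng, n, k, missing_rate=0.15)
            d = ps.gower_block_distance(table)
            scales = [table.meta.loc[t, "scale"] for t in table.values.columns]
            cols = [
                [None if np.isnan(v) else float(v) for v in table.values[t]]
                for t in table.values.columns
            ]
            for i in range(n):
                for j in range(i + 1, n):
                    expect = gower_pair(
                        [c[i] for c in cols], [c[j] for c in cols], scales, cols
                    )
                    if expect is None:
                        assert d.mask[i, j]
                    else:
                        assert d.values[i, j] == pytest.approx(expect)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_bounded_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        table = random_trait_table(rng, int(rng.integers(3, 8)), 3)
        d = ps.gower_block_distance(table)
        vals = d.values[~d.mask]
        assert (vals >= -1e-12).all() and (vals <= 1 + 1e-12).all()
        np.testing.assert_allclose(d.values, d.values.T)

    def test_trait_permutation_invariance(self, rng):
        table = random_trait_table(rng, 6, 4, missing_rate=0)
        perm = table.restrict(list(reversed(table.values.columns)))
        np.testing.assert_allclose(
            ps.gower_block_distance(table).values,
            ps.gower_block_distance(perm).values,
        )


class TestCombineBlocks:
    def _dm(self, v, mask=None):
        arr = np.array([[0.0, v], [v, 0.0]])
        m = None
        if mask:
            m = np.array([[False, True], [True, False]])
        return ps.DistanceMatrix(["a", "b"], arr, m)

    def test_unweighted_mean(self):
        d = ps.combine_blocks([self._dm(0.2), self._dm(0.4), self._dm(0.6)])
        assert d.values[0, 1] == pytest.approx(0.4)

    def test_masked_block_dropped(self):
        d = ps.combine_blocks([self._dm(0.2), self._dm(0.9, mask=True),
                               self._dm(0.6)])
        assert d.values[0, 1] == pytest.approx(0.4)
        assert not d.mask[0, 1]

    def test_identical_blocks_identity(self, rng):
        table = random_trait_table(rng, 5, 3, missing_rate=0)
        m = ps.gower_block_distance(table)
        combined = ps.combine_blocks([m, m, m])
        np.testing.assert_allclose(combined.values, m.values)

    def test_label_mismatch(self):
        a = ps.DistanceMatrix(["a", "b"], np.zeros((2, 2)))
        c = ps.DistanceMatrix(["a", "c"], np.zeros((2, 2)))
        with pytest.raises(ps.ValidationError):
            ps.combine_blocks([a, c])


class TestCophenetic:
    def _phylo(self, newick, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text(newick)
        return ps.read_phylogeny(path)

    def test_path_sums(self, tmp_path):
        tree = self._phylo("((A:1,B:1):1,C:2);", tmp_path)
        d = ps.cophenetic_distance(tree, normalize=False)
        frame = d.to_frame()
        assert frame.loc["A", "B"] == pytest.approx(2.0)
        assert frame.loc["A", "C"] == pytest.approx(4.0)
        assert frame.loc["B", "C"] == pytest.approx(4.0)

    def test_normalised_scale(self, tmp_path):
        tree = self._phylo("((A:1,B:1):1,C:2);", tmp_path)
        d = ps.cophenetic_distance(tree, normalize=True).to_frame()
        assert d.loc["A", "B"] == pytest.approx(0.5)
        assert d.loc["A", "C"] == pytest.approx(1.0)

    def test_star_tree_equal_branches(self, tmp_path):
        tree = self._phylo("(A:3,B:3,C:3,D:3);", tmp_path)
        d = ps.cophenetic_distance(tree, normalize=False)
        off = d.values[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 6.0)

    def test_random_trees_match_path_oracle(self, rng, tmp_path):
        for rep in range(20):
            from oracles import random_tree_tuples

            tup = random_tree_tuples(rng, int(rng.integers(3, 9)))
            tree = self._phylo(tree_to_newick(tup), tmp_path)
            d = ps.cophenetic_distance(tree, normalize=False).to_frame()
            for (a, b), expect in cophenetic_brute(tup).items():
                assert d.loc[a, b] == pytest.approx(expect)


class TestMpd:
    def _dist(self, labels, pairs):
        n = len(labels)
        arr = np.zeros((n, n))
        for (i, j), v in pairs.items():
            arr[i, j] = arr[j, i] = v
        return ps.DistanceMatrix(labels, arr)

    def test_two_and_three_species(self):
        d = self._dist(list("abc"), {(0, 1): 0.2, (0, 2): 0.4, (1, 2): 0.6})
        assert ps.mpd(["a", "b"], d) == pytest.approx(0.2)
        assert ps.mpd(["a", "b", "c"], d) == pytest.approx(0.4)

    def test_singleton_nan_with_warning(self):
        d = self._dist(["a", "b"], {(0, 1): 0.3})
        with pytest.warns(UserWarning):
            assert np.isnan(ps.mpd(["a"], d))

    def test_unknown_species_named(self):
        d = self._dist(["a", "b"], {(0, 1): 0.3})
        with pytest.raises(ps.ValidationError, match="zz"):
            ps.mpd(["a", "zz"], d)

    def test_matches_bruteforce_and_vectorised(self, rng):
        labels = [f"s{i}" for i in range(15)]
        arr = rng.uniform(0, 1, (15, 15))
        arr = (arr + arr.T) / 2
        np.fill_diagonal(arr, 0)
        d = ps.DistanceMatrix(labels, arr)
        lookup = {
            (labels[i], labels[j]): arr[i, j]
            for i in range(15)
            for j in range(15)
        }
        occ_rows = (rng.random((30, 15)) < 0.4).astype(int)
        occ = ps.OccupancyMatrix(
            pd.DataFrame(occ_rows, columns=labels,
                         index=[f"p{i}" for i in range(30)])
        )
        vec = ps.mpd_all(occ, d)
        for p in occ.patch_ids:
            comm = occ.community(p)
            expect = mpd_brute(comm, lookup)
            if expect is None:
                assert np.isnan(vec[p])
            else:
                assert vec[p] == pytest.approx(expect)
                assert ps.mpd(comm, d) == pytest.approx(expect)

    def test_mpd_insensitive_to_richness_by_construction(self, rng):
        """Adding a species at the community's mean distance profile leaves
        MPD unchanged even though SD grows."""
        labels = list("abcd")
        base = 0.3
        arr = np.full((4, 4), base)
        np.fill_diagonal(arr, 0)
        d = ps.DistanceMatrix(labels, arr)
        assert ps.mpd(["a", "b"], d) == pytest.approx(ps.mpd(labels, d))


class TestRichnessAndCM:
    def test_richness_counts_and_additivity(self):
        df = pd.DataFrame(
            [[0, 0, 0, 0], [1, 0, 1, 1], [1, 1, 0, 0], [0, 0, 1, 1]],
            index=[f"p{i}" for i in range(4)],
            columns=list("wxyz"),
        )
        occ = ps.OccupancyMatrix(df)
        assert list(ps.species_richness(occ)) == [0, 3, 2, 2]
        # disjoint union of p2 and p3 has SD = SD(p2) + SD(p3)
        union = (df.loc["p2"] | df.loc["p3"]).to_frame().T
        assert int(union.sum(axis=1).iloc[0]) == 4

    def test_community_mean_skips_missing(self):
        row = pd.Series([1, 1, 1, 0], index=list("abcd"))
        vals = pd.Series([1.0, np.nan, 3.0, 99.0], index=list("abcd"))
        assert ps.community_mean(row, vals) == pytest.approx(2.0)
        single = pd.Series([1, 0, 0, 0], index=list("abcd"))
        assert ps.community_mean(single, vals) == pytest.approx(1.0)

    def test_community_mean_no_values_warns(self):
        row = pd.Series([1, 0], index=list("ab"))
        vals = pd.Series([np.nan, 5.0], index=list("ab"))
        with pytest.warns(UserWarning):
            assert np.isnan(ps.community_mean(row, vals))


class TestDiversityProfile:
    def test_hand_computed_fixture(self, mixed_traits):
        occ = ps.OccupancyMatrix(
            pd.DataFrame(
                [[1, 1, 0, 0, 0]], index=["p1"],
                columns=mixed_traits.species_ids,
            )
        )
        fdist = ps.gower_block_distance(mixed_traits)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = ps.diversity_profile(occ, fdist, None, mixed_traits)
        assert prof.df.loc["p1", "SD"] == 2
        assert prof.df.loc["p1", "FD"] == pytest.approx(fdist.values[0, 1])
        assert prof.df.loc["p1", "CM_height"] == pytest.approx(4.5)

    def test_species_order_invariance(self, small_study):
        occ = small_study.occupancy
        fdist = ps.gower_block_distance(
            small_study.traits.restrict(
                small_study.traits.traits_in_block("seed"))
        )
        prof1 = ps.diversity_profile(occ, fdist)
        perm = list(reversed(occ.species_ids))
        occ2 = ps.OccupancyMatrix(occ.df[perm])
        prof2 = ps.diversity_profile(occ2, fdist)
        pd.testing.assert_frame_equal(prof1.df, prof2.df)

    def test_identical_rows_identical_profiles(self, mixed_traits):
        row = [1, 0, 1, 0, 1]
        occ = ps.OccupancyMatrix(
            pd.DataFrame([row, row], index=["p1", "p2"],
                         columns=mixed_traits.species_ids)
        )
        fdist = ps.gower_block_distance(mixed_traits)
        prof = ps.diversity_profile(occ, fdist, None, mixed_traits)
        assert prof.df.loc["p1"].equals(prof.df.loc["p2"])

    def test_single_block_fd_equals_block_mpd(self, rng):
        table = random_trait_table(rng, 8, 3, missing_rate=0)
        block = ps.gower_block_distance(table)
        combined = ps.combine_blocks([block])
        occ = ps.OccupancyMatrix(
            pd.DataFrame((rng.random((5, 8)) < 0.6).astype(int),
                         index=[f"p{i}" for i in range(5)],
                         columns=table.species_ids)
        )
        np.testing.assert_allclose(
            ps.mpd_all(occ, combined), ps.mpd_all(occ, block)
        )
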