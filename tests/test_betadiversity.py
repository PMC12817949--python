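import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ecoassembly.betadiversity import (
    anosim,
    bray_curtis_matrix,
    permanova,
    rjsd,
)
from ecoassembly.core_io import CommunityTable, DistanceMatrix, SampleMetadata


class TestBrayCurtis:
    def test_identical_and_disjoint_columns(self):
        df = pd.DataFrame(
            {"a": [3, 1, 0], "b": [3, 1, 0], "c": [0, 0, 7]}, index=["x", "y", "z"]
        )
        dm = bray_curtis_matrix(CommunityTable(df))
        assert dm["a", "b"] == 0.0
        assert dm["a", "c"] == 1.0

    def test_formula_example(self):
        df = pd.DataFrame({"a": [6, 2], "b": [2, 2]}, index=["x", "y"])
        dm = bray_curtis_matrix(CommunityTable(df))
        assert math.isclose(dm["a", "b"], 1.0 / 3.0, rel_tol=1e-12)

    def test_matches_skbio(self, random_counts):
        skbio_distance = pytest.importorskip("skbio.diversity")
        ours = bray_curtis_matrix(random_counts)
        theirs = skbio_distance.beta_diversity(
            "braycurtis", random_counts.values.T, ids=random_counts.sample_ids
        )
        np.testing.assert_allclose(ours.values, theirs.data, atol=1e-12)

    def test_zero_sample_rejected(self):
        df = pd.DataFrame({"a": [1, 1], "b": [0, 0]}, index=["x", "y"])
        with pytest.raises(ValueError, match="b"):
            bray_curtis_matrix(CommunityTable(df))


class TestRJSD:
    def test_identical_is_zero(self):
        assert rjsd([0.5, 0.5], [0.5, 0.5]) == 0.0

    def test_disjoint_reaches_sqrt_ln2(self):
        assert math.isclose(rjsd([1, 0], [0, 1]), math.sqrt(math.log(2)), rel_tol=1e-12)

    def test_matches_term_by_term_oracle(self):
        x = np.array([0.5, 0.5])
        y = np.array([0.25, 0.75])
        m = (x + y) / 2
        expected = math.sqrt(
            0.5 * sum(xi * math.log(xi / mi) for xi, mi in zip(x, m) if xi > 0)
            + 0.5 * sum(yi * math.log(yi / mi) for yi, mi in zip(y, m) if yi > 0)
        )
        assert math.isclose(rjsd(x, y), expected, rel_tol=1e-12)

    def test_range_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.dirichlet(np.ones(6))
            y = rng.dirichlet(np.ones(6))
            v = rjsd(x, y)
            assert 0.0 <= v <= math.sqrt(math.log(2)) + 1e-12

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            rjsd([-0.1, 1.1], [0.5, 0.5])


def _dm_from_square(values, ids):
    return DistanceMatrix(ids, np.asarray(values, dtype=float))


class TestANOSIM:
    def test_fully_tied_distances_give_zero(self):
        ids = ["a", "b", "c", "d"]
        m = np.ones((4, 4)) - np.eye(4)
        meta = SampleMetadata(pd.Series(["g1", "g1", "g2", "g2"], index=ids))
        res = anosim(_dm_from_square(m, ids), meta, n_perm=99, seed=0)
        assert res.statistic == 0.0

    def test_perfect_separation_gives_one(self):
        ids = ["a", "b", "c", "d"]
        m = np.array(
            [[0, 0.1, 0.9, 0.9], [0.1, 0, 0.9, 0.9], [0.9, 0.9, 0, 0.1], [0.9, 0.9, 0.1, 0]]
        )
        meta = SampleMetadata(pd.Series(["g1", "g1", "g2", "g2"], index=ids))
        res = anosim(_dm_from_square(m, ids), meta, n_perm=99, seed=0)
        assert math.isclose(res.statistic, 1.0, rel_tol=1e-12)

    def test_p_matches_exhaustive_enumeration(self):
        # 2+2 design: 3 distinct splits; enumerate R for all of them
        ids = ["a", "b", "c", "d"]
        rng = np.random.default_rng(5)
        m = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        vals = rng.random(6)
        m[iu] = vals
        m = m + m.T
        dm = _dm_from_square(m, ids)
        meta = SampleMetadata(pd.Series(["g1", "g1", "g2", "g2"], index=ids))
        from scipy.stats import rankdata

        ranks = rankdata(m[iu])

        def r_for(split):
            within = np.array(
                [split[i] == split[j] for i, j in zip(iu[0], iu[1])]
            )
            return (ranks[~within].mean() - ranks[within].mean()) / (6 / 2)

        obs = r_for(["g1", "g1", "g2", "g2"])
        all_r = [
            r_for(p)
            for p in set(itertools.permutations(["g1", "g1", "g2", "g2"]))
        ]
        exact_p = sum(1 for r in all_r if r >= obs - 1e-12) / len(all_r)
        res = anosim(dm, meta, n_perm=4999, seed=1)
        assert abs(res.p_value - exact_p) < 0.05

    def test_matches_skbio_statistic(self, random_counts, two_group_meta):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        import skbio

        dm = bray_curtis_matrix(random_counts)
        ours = anosim(dm, two_group_meta, n_perm=99, seed=0)
        sk = skbio_stats.anosim(
            skbio.DistanceMatrix(dm.values, ids=dm.ids),
            grouping=list(two_group_meta.labels_for(dm.ids)),
            permutations=99,
        )
        assert math.isclose(ours.statistic, sk["test statistic"], rel_tol=1e-9)

    def test_singleton_group_rejected(self):
        ids = ["a", "b", "c"]
        m = np.ones((3, 3)) - np.eye(3)
        meta = SampleMetadata(pd.Series(["g1", "g1", "g2"], index=ids))
        with pytest.raises(ValueError, match="fewer than 2"):
            anosim(_dm_from_square(m, ids), meta, n_perm=9, seed=0)


class TestPERMANOVA:
    def test_hand_computed_sums_of_squares(self):
        # 5 samples, groups (g1: a,b) (g2: c,d,e)
        ids = ["a", "b", "c", "d", "e"]
        m = np.array(
            [
                [0, 1, 4, 4, 4],
                [1, 0, 4, 4, 4],
                [4, 4, 0, 2, 2],
                [4, 4, 2, 0, 2],
                [4, 4, 2, 2, 0],
            ],
            dtype=float,
        )
        meta = SampleMetadata(pd.Series(["g1", "g1", "g2", "g2", "g2"], index=ids))
        res = permanova(_dm_from_square(m, ids), meta, n_perm=99, seed=0)
        # SS_total = (1/5) * sum d^2 over pairs = (1 + 6*16 + 3*4)/5 = 109/5
        # SS_within = 1/2 * 1 + (1/3)(4+4+4) = 0.5 + 4 = 4.5
        ss_total = 109 / 5
        ss_within = 4.5
        f_expected = ((ss_total - ss_within) / 1) / (ss_within / 3)
        assert math.isclose(res.statistic, f_expected, rel_tol=1e-12)
        assert math.isclose(res.r_squared, (ss_total - ss_within) / ss_total, rel_tol=1e-12)

    def test_duplicate_point_groups_r2_one(self):
        ids = ["a", "b", "c", "d"]
        m = np.array(
            [[0, 0, 3, 3], [0, 0, 3, 3], [3, 3, 0, 0], [3, 3, 0, 0]], dtype=float
        )
        meta = SampleMetadata(pd.Series(["g1", "g1", "g2", "g2"], index=ids))
        res = permanova(_dm_from_square(m, ids), meta, n_perm=99, seed=0)
        assert res.statistic == math.inf
        assert res.r_squared == 1.0
        assert 0 < res.p_value <= 1

    def test_matches_skbio_statistic(self, random_counts, two_group_meta):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        import skbio

        dm = bray_curtis_matrix(random_counts)
        ours = permanova(dm, two_group_meta, n_perm=99, seed=0)
        sk = skbio_stats.permanova(
            skbio.DistanceMatrix(dm.values, ids=dm.ids),
            grouping=list(two_group_meta.labels_for(dm.ids)),
            permutations=99,
        )
        assert math.isclose(ours.statistic, sk["test statistic"], rel_tol=1e-9)


class TestInvariances:
    def test_statistics_invariant_to_relabeling_and_order(self, random_counts, two_group_meta):
        dm = bray_curtis_matrix(random_counts)
        res1 = anosim(dm, two_group_meta, n_perm=49, seed=0)
        relabeled = SampleMetadata(
            two_group_meta.groups.map({"A": "X", "B": "Y"})
        )
        res2 = anosim(dm, relabeled, n_perm=49, seed=0)
        assert math.isclose(res1.statistic, res2.statistic, rel_tol=1e-12)

        order = dm.ids[::-1]
        idx = [dm.ids.index(s) for s in order]
        dm_rev = DistanceMatrix(order, dm.values[np.ix_(idx, idx)])
        res3 = permanova(dm_rev, two_group_meta, n_perm=49, seed=0)
        res4 = permanova(dm, two_group_meta, n_perm=49, seed=0)
        assert math.isclose(res3.statistic, res4.statistic, rel_tol=1e-12)

    def test_permutation_p_never_zero(self, random_counts, two_group_meta):
        dm = bray_curtis_matrix(random_counts)
        for res in (
            anosim(dm, two_group_meta, n_perm=9, seed=0),
            permanova(dm, two_group_meta, n_perm=9, seed=0),
        ):
            assert res.p_value >= 1 / 10
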