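import itertools
import logging
import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from ecoassembly.assembly import (
    NullModelConfig,
    bmntd,
    bnti,
    group_bnti_summary,
    partition_processes,
    patristic_matrix,
    raup_crick_bray,
)
from ecoassembly.core_io import CommunityTable, DistanceMatrix, SampleMetadata


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def bmntd_oracle(counts: np.ndarray, dist: np.ndarray) -> float:
    """Independent betaMNTD for one sample pair, written as explicit loops."""
    n_taxa = counts.shape[0]
    total = 0.0
    for j, k in ((0, 1), (1, 0)):
        present_j = [i for i in range(n_taxa) if counts[i, j] > 0]
        present_k = [i for i in range(n_taxa) if counts[i, k] > 0]
        col_sum = sum(counts[i, j] for i in present_j)
        for i in present_j:
            nearest = min(dist[i, i2] for i2 in present_k)
            total += 0.5 * (counts[i, j] / col_sum) * nearest
    return total


FOUR_TAXON_TREE = "((A:1.0,B:2.0):1.0,(C:3.0,D:1.0):2.0);"


class TestBMNTD:
    def test_identical_communities_are_zero(self):
        tree = tree_from_newick(FOUR_TAXON_TREE)
        df = pd.DataFrame({"S1": [1, 2, 3, 4], "S2": [1, 2, 3, 4]}, index=list("ABCD"))
        dm = bmntd(CommunityTable(df), tree)
        assert dm["S1", "S2"] == 0.0

    def test_singleton_communities_give_patristic_distance(self):
        tree = tree_from_newick(FOUR_TAXON_TREE)
        df = pd.DataFrame({"S1": [5, 0, 0, 0], "S2": [0, 0, 7, 0]}, index=list("ABCD"))
        dm = bmntd(CommunityTable(df), tree)
        # d(A, C) = 1 + 1 + 2 + 3 = 7
        assert math.isclose(dm["S1", "S2"], 7.0, rel_tol=1e-12)

    def test_matches_hand_oracle_on_four_taxon_fixture(self):
        tree = tree_from_newick(FOUR_TAXON_TREE)
        df = pd.DataFrame({"S1": [4, 1, 0, 1], "S2": [0, 2, 3, 0]}, index=list("ABCD"))
        table = CommunityTable(df)
        dist = patristic_matrix(tree, table.taxon_ids)
        expected = bmntd_oracle(df.to_numpy().astype(float), dist)
        dm = bmntd(table, tree)
        assert math.isclose(dm["S1", "S2"], expected, rel_tol=1e-12)

    def test_invariant_to_taxa_absent_from_both_samples(self):
        tree = tree_from_newick(FOUR_TAXON_TREE)
        df_full = pd.DataFrame({"S1": [4, 1, 0, 0], "S2": [0, 2, 3, 0]}, index=list("ABCD"))
        df_trim = df_full.drop(index="D")
        v_full = bmntd(CommunityTable(df_full), tree)["S1", "S2"]
        v_trim = bmntd(CommunityTable(df_trim), tree)["S1", "S2"]
        assert math.isclose(v_full, v_trim, rel_tol=1e-12)

    def test_missing_taxon_named_in_error(self):
        tree = tree_from_newick(FOUR_TAXON_TREE)
        df = pd.DataFrame({"S1": [1, 1], "S2": [1, 1]}, index=["A", "ZZZ"])
        with pytest.raises(KeyError, match="ZZZ"):
            bmntd(CommunityTable(df), tree)


class TestBNTI:
    def test_exhaustive_null_matches_enumeration_oracle(self):
        """betaNTI from the fully enumerated tip-permutation null agrees with
        an independent loop-based enumeration to machine precision."""
        newick = "(((A:1,B:1.5):0.5,(C:2,D:0.5):1):0.5,(E:1,F:2):1.5);"
        tree = tree_from_newick(newick)
        df = pd.DataFrame(
            {"S1": [3, 1, 0, 2, 0, 0], "S2": [0, 0, 4, 1, 2, 0]},
            index=list("ABCDEF"),
        )
        table = CommunityTable(df)
        dist = patristic_matrix(tree, table.taxon_ids)
        counts = df.to_numpy().astype(float)

        obs = bmntd_oracle(counts, dist)
        nulls = []
        for perm in itertools.permutations(range(6)):
            permuted = dist[np.ix_(perm, perm)]
            nulls.append(bmntd_oracle(counts, permuted))
        nulls = np.array(nulls)
        expected = (obs - nulls.mean()) / nulls.std(ddof=0)

        config = NullModelConfig(exhaustive=True)
        z = bnti(table, tree, config)["S1", "S2"]
        assert math.isclose(z, expected, abs_tol=1e-12)

    def test_star_tree_disjoint_singletons_degenerate(self):
        tree = tree_from_newick("(A:1,B:1,C:1,D:1);")
        df = pd.DataFrame({"S1": [9, 0, 0, 0], "S2": [0, 9, 0, 0]}, index=list("ABCD"))
        z = bnti(CommunityTable(df), tree, NullModelConfig(n_randomizations=50, seed=0))
        assert math.isnan(z["S1", "S2"])

    def test_seed_stability_within_monte_carlo_tolerance(self):
        rng = np.random.default_rng(8)
        from ecoassembly.simulate import simulate_tree

        tree = simulate_tree(50, seed=4)
        taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        df = pd.DataFrame(
            rng.poisson(5.0, size=(50, 4)), index=taxa, columns=list("wxyz")
        )
        df.iloc[:25, :2] += 20  # structure so betaNTI is not trivially zero
        table = CommunityTable(df)
        z1 = bnti(table, tree, NullModelConfig(n_randomizations=999, seed=1))
        z2 = bnti(table, tree, NullModelConfig(n_randomizations=999, seed=2))
        assert np.nanmax(np.abs(z1.values - z2.values)) < 0.3

    def test_invalid_randomization_count_rejected(self):
        with pytest.raises(ValueError):
            NullModelConfig(n_randomizations=0)


class TestRaupCrick:
    def test_bounds_and_exact_symmetry(self, random_counts):
        rc = raup_crick_bray(random_counts, NullModelConfig(n_randomizations=99, seed=0))
        assert np.all(rc.values >= -1.0) and np.all(rc.values <= 1.0)
        assert np.array_equal(rc.values, rc.values.T)

    def test_identical_diverse_communities_give_strongly_negative_rc(self):
        rng = np.random.default_rng(3)
        n_taxa = 100
        pool = rng.dirichlet(np.ones(n_taxa))
        shared = rng.multinomial(2000, pool)
        cols = {"S1": shared, "S2": shared.copy()}
        for j in range(4):  # context samples so occurrence frequencies vary
            cols[f"C{j}"] = rng.multinomial(2000, pool)
        df = pd.DataFrame(cols, index=[f"T{i:03d}" for i in range(n_taxa)])
        rc = raup_crick_bray(
            CommunityTable(df), NullModelConfig(n_randomizations=999, seed=0)
        )
        assert rc["S1", "S2"] < -0.9

    def test_empty_sample_rejected(self):
        df = pd.DataFrame({"S1": [1, 1], "S2": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="S2"):
            raup_crick_bray(CommunityTable(df), NullModelConfig(n_randomizations=9))


class TestPartition:
    def _dm(self, ids, values):
        return DistanceMatrix(ids, values)

    def test_six_pair_hand_fixture(self):
        ids = ["a", "b", "c", "d"]
        bnti_vals = np.zeros((4, 4))
        rc_vals = np.zeros((4, 4))
        pair_data = {
            ("a", "b"): (2.5, 0.0),
            ("a", "c"): (-3.0, 0.0),
            ("a", "d"): (0.1, 0.99),
            ("b", "c"): (1.9, -0.99),
            ("b", "d"): (-0.5, 0.2),
            ("c", "d"): (0.3, 0.5),
        }
        for (x, y), (b, r) in pair_data.items():
            i, j = ids.index(x), ids.index(y)
            bnti_vals[i, j] = bnti_vals[j, i] = b
            rc_vals[i, j] = rc_vals[j, i] = r
        part = partition_processes(self._dm(ids, bnti_vals), self._dm(ids, rc_vals))
        assert part.fractions == {
            "heterogeneous selection": pytest.approx(1 / 6),
            "homogeneous selection": pytest.approx(1 / 6),
            "dispersal limitation": pytest.approx(1 / 6),
            "homogenizing dispersal": pytest.approx(1 / 6),
            "drift": pytest.approx(2 / 6),
        }
        assert abs(sum(part.fractions.values()) - 1.0) < 1e-12

    def test_single_rule_fires(self):
        ids = ["a", "b", "c"]
        b = np.full((3, 3), 3.0)
        np.fill_diagonal(b, 0.0)
        part = partition_processes(self._dm(ids, b), self._dm(ids, np.zeros((3, 3))))
        assert part.fractions["heterogeneous selection"] == 1.0

    def test_degenerate_pairs_excluded_from_denominator(self):
        ids = ["a", "b", "c"]
        b = np.zeros((3, 3))
        b[0, 1] = b[1, 0] = np.nan
        b[0, 2] = b[2, 0] = 3.0
        b[1, 2] = b[2, 1] = 3.0
        part = partition_processes(self._dm(ids, b), self._dm(ids, np.zeros((3, 3))))
        assert part.n_degenerate == 1
        assert part.fractions["heterogeneous selection"] == 1.0

    def test_mismatched_sample_sets_rejected(self):
        a = self._dm(["a", "b"], np.zeros((2, 2)))
        b = self._dm(["a", "c"], np.zeros((2, 2)))
        with pytest.raises(ValueError, match="different samples"):
            partition_processes(a, b)


class TestGroupSummary:
    def _setup(self):
        ids = [f"s{i}" for i in range(6)]
        rng = np.random.default_rng(0)
        m = np.zeros((6, 6))
        iu = np.triu_indices(6, 1)
        m[iu] = rng.normal(size=15)
        m = m + m.T
        dm = DistanceMatrix(ids, m, metric="bNTI")
        meta = SampleMetadata(
            pd.Series(["g1"] * 3 + ["g2"] * 2 + ["g3"], index=ids)
        )
        return dm, meta

    def test_within_group_pair_counts(self, caplog):
        dm, meta = self._setup()
        with caplog.at_level(logging.WARNING, logger="ecoassembly"):
            out = group_bnti_summary(dm, meta)
        assert out["g1"]["n_pairs"] == 3  # C(3,2)
        assert out["g2"]["n_pairs"] == 1
        assert out["g3"]["n_pairs"] == 0 and "g3" in caplog.text

    def test_invariant_to_sample_order(self):
        dm, meta = self._setup()
        order = dm.ids[::-1]
        idx = [dm.ids.index(s) for s in order]
        dm_rev = DistanceMatrix(order, dm.values[np.ix_(idx, idx)], metric="bNTI")
        a = group_bnti_summary(dm, meta)
        b = group_bnti_summary(dm_rev, meta)
        for g in ("g1", "g2"):
            assert sorted(a[g]["values"]) == pytest.approx(sorted(b[g]["values"]))

    def test_vs_reference_mode_reports_rank_test(self):
        dm, meta = self._setup()
        out = group_bnti_summary(dm, meta, mode="vs_reference", reference="g1")
        assert "rank_test_vs_reference" in out["g2"]
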