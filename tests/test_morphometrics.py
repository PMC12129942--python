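"""Gower distance, UPGMA, trait PCA and diagnosability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cotodelim.datatypes import Trait, TraitTable
from cotodelim.morphometrics import (DistanceMatrix, count_diagnostic_traits,
                                     gower_matrix, trait_pca, upgma_cluster)

from _oracles import diagnostic_count_oracle, upgma_oracle


def make_table(df, kinds):
    schema = [Trait(c, kinds[c]) for c in df.columns]
    return TraitTable(df.astype(float), schema)


class TestGower:
    def test_identical_rows_distance_zero(self):
        df = pd.DataFrame({"len": [3.0, 3.0], "col": [1, 1]},
                          index=["a", "b"])
        D = gower_matrix(make_table(df, {"len": "quantitative",
                                         "col": "qualitative"}))
        assert D.matrix[0, 1] == 0.0

    def test_hand_computed_mixed_example(self):
        # A(len=0, red), B(len=5, red), C(len=10, blue)
        df = pd.DataFrame({"len": [0.0, 5.0, 10.0], "col": [0, 0, 1]},
                          index=list("ABC"))
        D = gower_matrix(make_table(df, {"len": "quantitative",
                                         "col": "qualitative"}))
        assert np.isclose(D.matrix[0, 1], (5 / 10 + 0) / 2)  # 0.25
        assert np.isclose(D.matrix[0, 2], (10 / 10 + 1) / 2)  # 1.0

    def test_disjoint_qualitative_states_give_distance_one(self):
        df = pd.DataFrame({"a": [0, 1, 2], "b": [3, 4, 5]},
                          index=list("xyz"))
        D = gower_matrix(make_table(df, {"a": "qualitative",
                                         "b": "qualitative"}))
        off = D.matrix[~np.eye(3, dtype=bool)]
        assert (off == 1.0).all()

    def test_pair_sharing_no_trait_is_error(self):
        df = pd.DataFrame({"a": [1.0, np.nan], "b": [np.nan, 2.0]},
                          index=["u", "v"])
        with pytest.raises(ValueError, match="share no observed trait"):
            gower_matrix(make_table(df, {"a": "quantitative",
                                         "b": "quantitative"}))

    def test_missing_values_renormalize_by_shared_traits(self):
        df = pd.DataFrame({"a": [0.0, 10.0], "b": [1, np.nan],
                           "c": [0, 1]}, index=["u", "v"])
        D = gower_matrix(make_table(df, {"a": "quantitative",
                                         "b": "qualitative",
                                         "c": "qualitative"}))
        assert np.isclose(D.matrix[0, 1], (1.0 + 1.0) / 2)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_bounds_symmetry_and_reorder_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        df = pd.DataFrame(
            {"q1": rng.uniform(0, 10, n), "q2": rng.uniform(-5, 5, n),
             "c1": rng.integers(0, 3, n)},
            index=[f"u{i}" for i in range(n)])
        T = make_table(df, {"q1": "quantitative", "q2": "quantitative",
                            "c1": "qualitative"})
        D = gower_matrix(T)
        assert (D.matrix >= -1e-12).all() and (D.matrix <= 1 + 1e-12).all()
        perm = rng.permutation(n)
        Dp = gower_matrix(make_table(df.iloc[perm], {
            "q1": "quantitative", "q2": "quantitative",
            "c1": "qualitative"}))
        assert np.allclose(Dp.matrix, D.matrix[np.ix_(perm, perm)])


class TestUpgma:
    def test_two_units_merge_at_half_distance(self):
        D = DistanceMatrix(["a", "b"], np.array([[0.0, 2.0], [2.0, 0.0]]))
        dend = upgma_cluster(D)
        assert np.isclose(dend.merge_heights[-1], 1.0)

    def test_hand_computed_three_unit_merges(self):
        m = np.array([[0.0, 2.0, 8.0], [2.0, 0.0, 8.0], [8.0, 8.0, 0.0]])
        dend = upgma_cluster(DistanceMatrix(list("ABC"), m))
        assert np.allclose(sorted(dend.merge_heights), [1.0, 4.0])

    def test_matches_naive_oracle_on_random_matrices(self, rng):
        for _ in range(10):
            n = 6
            x = rng.uniform(0, 1, (n, 4))
            m = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
            labels = [f"u{i}" for i in range(n)]
            dend = upgma_cluster(DistanceMatrix(labels, m))
            expected = sorted(h for _, h in upgma_oracle(labels, m))
            assert np.allclose(sorted(dend.merge_heights), expected)

    def test_cophenetic_matrix_is_ultrametric(self, rng):
        x = rng.uniform(0, 1, (6, 3))
        m = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        dend = upgma_cluster(DistanceMatrix([f"u{i}" for i in range(6)], m))
        C = dend.cophenetic().matrix
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert C[i, j] <= max(C[i, k], C[k, j]) + 1e-9

    def test_merge_heights_non_decreasing(self, rng):
        x = rng.uniform(0, 1, (8, 3))
        m = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        dend = upgma_cluster(DistanceMatrix([f"u{i}" for i in range(8)], m))
        assert (np.diff(dend.merge_heights) >= -1e-12).all()

    def test_newick_export_parses_back(self):
        m = np.array([[0.0, 2.0, 8.0], [2.0, 0.0, 8.0], [8.0, 8.0, 0.0]])
        dend = upgma_cluster(DistanceMatrix(list("ABC"), m))
        import dendropy
        t = dendropy.Tree.get(data=dend.to_newick(), schema="newick")
        assert {l.taxon.label for l in t.leaf_node_iter()} == set("ABC")


class TestTraitPca:
    def test_single_varying_trait_is_whole_variance(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5, 5, 5]},
                          index=list("xyz"))
        _, frac, _ = trait_pca(make_table(df, {"a": "quantitative",
                                               "b": "quantitative"}))
        assert np.isclose(frac[0], 1.0)

    def test_eigenvalues_match_2x2_closed_form(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 4.0, 5.0],
                           "b": [2.0, 1.0, 5.0, 3.0]}, index=list("wxyz"))
        _, frac, _ = trait_pca(make_table(df, {"a": "quantitative",
                                               "b": "quantitative"}))
        r = np.corrcoef(df["a"], df["b"])[0, 1]
        expected = np.array([1 + abs(r), 1 - abs(r)]) / 2
        assert np.allclose(frac, expected, atol=1e-9)

    def test_contributions_sum_to_100_per_pc(self, rng):
        df = pd.DataFrame(rng.uniform(0, 1, (8, 5)),
                          columns=[f"t{i}" for i in range(5)],
                          index=[f"u{i}" for i in range(8)])
        _, _, contrib = trait_pca(
            make_table(df, {c: "quantitative" for c in df.columns}))
        assert np.allclose(contrib.sum(axis=0), 100.0, atol=1e-9)


class TestDiagnosability:
    kinds = {"len": "quantitative", "ind": "qualitative"}

    def test_two_discontinuous_traits_make_diagnosable(self):
        # leaf length [6,10] vs [12,18] mm, tomentose vs glabrous
        df = pd.DataFrame({"len": [6.0, 10.0, 12.0, 18.0],
                           "ind": [0, 0, 1, 1]},
                          index=["a1", "a2", "b1", "b2"])
        T = make_table(df, self.kinds)
        n, diagnosable, verdicts = count_diagnostic_traits(
            T, ["a1", "a2"], ["b1", "b2"])
        assert n == 2 and diagnosable
        assert all(v.discontinuous for v in verdicts)

    def test_identical_tables_are_not_diagnosable(self):
        df = pd.DataFrame({"len": [1.0, 2.0, 1.0, 2.0],
                           "ind": [0, 1, 0, 1]},
                          index=["a1", "a2", "b1", "b2"])
        n, diagnosable, _ = count_diagnostic_traits(
            make_table(df, self.kinds), ["a1", "a2"], ["b1", "b2"])
        assert n == 0 and not diagnosable

    def test_overlapping_intervals_not_discontinuous(self):
        df = pd.DataFrame({"len": [1.0, 5.0, 4.0, 9.0]},
                          index=["a1", "a2", "b1", "b2"])
        n, _, _ = count_diagnostic_traits(
            make_table(df, {"len": "quantitative"}),
            ["a1", "a2"], ["b1", "b2"])
        assert n == 0

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(20):
            kinds = {}
            cols = {}
            for t in range(5):
                name = f"t{t}"
                if rng.random() < 0.5:
                    kinds[name] = "quantitative"
                    cols[name] = rng.uniform(0, 4, 8)
                else:
                    kinds[name] = "qualitative"
                    cols[name] = rng.integers(0, 3, 8).astype(float)
            df = pd.DataFrame(cols, index=[f"u{i}" for i in range(8)])
            ua, ub = [f"u{i}" for i in range(4)], [f"u{i}"
                                                  for i in range(4, 8)]
            n, _, _ = count_diagnostic_traits(make_table(df, kinds), ua, ub)
            assert n == diagnostic_count_oracle(df, kinds, ua, ub)

    def test_symmetric_in_taxon_arguments(self, rng):
        df = pd.DataFrame({"len": rng.uniform(0, 10, 6),
                           "ind": rng.integers(0, 2, 6).astype(float)},
                          index=[f"u{i}" for i in range(6)])
        T = make_table(df, self.kinds)
        a, b = ["u0", "u1", "u2"], ["u3", "u4", "u5"]
        assert count_diagnostic_traits(T, a, b)[0] == \
            count_diagnostic_traits(T, b, a)[0]
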