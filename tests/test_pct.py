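import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import special

from toxclust.pct import (
    PCTParams,
    PCTree,
    SplitTest,
    assign,
    cluster_variance,
    f_test_accept,
    induce_tree,
    split_leaf_by_feature,
    variance_reduction,
)

from conftest import make_feature_matrix


def brute_force_root_split(values: pd.DataFrame, meta: dict, Y: np.ndarray,
                           min_leaf: int):
    """Enumerate every admissible test from first principles; return the set
    of optima (within 1e-9) as (column, threshold) pairs plus the best score.
    """
    n = len(values)
    best = -np.inf
    cands = []
    for col in values.columns:
        if meta[col]["kind"] == "binary":
            yes = values[col].to_numpy() >= 0.5
            options = [(None, yes)]
        else:
            x = values[col].to_numpy(float)
            uniq = np.unique(x)
            options = [(0.5 * (a + b), x <= 0.5 * (a + b))
                       for a, b in zip(uniq[:-1], uniq[1:])]
        for thr, yes in options:
            if yes.sum() < min_leaf or (~yes).sum() < min_leaf:
                continue
            red = variance_reduction(Y, [np.where(yes)[0], np.where(~yes)[0]])
            if red <= 0:
                continue
            cands.append((red, col, thr))
            best = max(best, red)
    optima = {(c, t) for r, c, t in cands if r >= best - 1e-9}
    return optima, best


class TestVariancePrimitives:
    def test_identical_rows_zero(self):
        assert cluster_variance([[1, 0, 1]] * 5) == 0.0

    def test_two_rows_single_endpoint(self):
        assert cluster_variance([[0.0], [1.0]]) == pytest.approx(0.25)

    def test_equals_pairwise_distance_form(self):
        rng = np.random.default_rng(0)
        Y = rng.integers(0, 2, size=(9, 4)).astype(float)
        n = len(Y)
        pairwise = sum(((Y[i] - Y[j]) ** 2).sum()
                       for i in range(n) for j in range(n))
        assert cluster_variance(Y) == pytest.approx(pairwise / (2 * n * n))

    def test_reduction_never_negative_and_decomposition(self):
        rng = np.random.default_rng(1)
        Y = rng.integers(0, 2, size=(12, 3)).astype(float)
        for _ in range(20):
            mask = rng.random(12) < 0.5
            if mask.all() or not mask.any():
                continue
            red = variance_reduction(Y, [np.where(mask)[0], np.where(~mask)[0]])
            assert red >= -1e-12

    def test_perfect_split_reduction_equals_parent_variance(self):
        Y = np.array([[0, 0]] * 4 + [[1, 1]] * 4, dtype=float)
        red = variance_reduction(Y, [np.arange(4), np.arange(4, 8)])
        assert red == pytest.approx(cluster_variance(Y))

    def test_identical_halves_zero_reduction(self):
        Y = np.array([[1, 0]] * 6, dtype=float)
        assert variance_reduction(Y, [np.arange(3), np.arange(3, 6)]) == 0.0

    def test_brute_force_equivalence_on_ten_row_fixture(self):
        rng = np.random.default_rng(3)
        Y = rng.integers(0, 2, size=(10, 4)).astype(float)
        for _ in range(30):
            mask = rng.random(10) < 0.5
            if mask.all() or not mask.any():
                continue
            idx1, idx2 = np.where(mask)[0], np.where(~mask)[0]
            # from definitions: Var(S) = (1/n) sum ||y - mean||^2
            def var(ix):
                sub = Y[ix]
                return ((sub - sub.mean(0)) ** 2).sum() / len(sub)
            expect = var(np.arange(10)) - (len(idx1) / 10 * var(idx1)
                                           + len(idx2) / 10 * var(idx2))
            assert variance_reduction(Y, [idx1, idx2]) == pytest.approx(expect)

    def test_degenerate_partition_rejected(self):
        Y = np.ones((4, 2))
        with pytest.raises(ValueError):
            variance_reduction(Y, [np.arange(4), np.array([], dtype=int)])


class TestFTest:
    def test_no_reduction_rejected(self):
        assert f_test_accept(0.3, 0.3, n=30, alpha=0.125) is False

    def test_perfect_split_accepted(self):
        assert f_test_accept(0.3, 0.0, n=6, alpha=0.125) is True

    def test_zero_parent_variance_rejected(self):
        assert f_test_accept(0.0, 0.0, n=6, alpha=0.125) is False

    def test_matches_closed_form_tail(self):
        # p = I_{d2/(d2 + d1 F)}(d2/2, d1/2), the regularized incomplete beta
        var_p, pooled, n, alpha = 0.25, 0.10, 20, 0.125
        F = var_p / pooled
        d1, d2 = n - 1, n - 2
        p = special.betainc(d2 / 2, d1 / 2, d2 / (d2 + d1 * F))
        assert f_test_accept(var_p, pooled, n, alpha) is bool(p <= alpha)
        assert p < 0.125  # this fixture is an accept

    @pytest.mark.parametrize("F", [1.1, 1.5, 2.0, 4.0])
    def test_decision_tracks_closed_form(self, F):
        n, alpha = 14, 0.125
        d1, d2 = n - 1, n - 2
        p = special.betainc(d2 / 2, d1 / 2, d2 / (d2 + d1 * F))
        assert f_test_accept(F, 1.0, n, alpha) is bool(p <= alpha)


def six_compound_fixture():
    ids = [f"m{i}" for i in range(6)]
    bits = np.array([[1, 0], [1, 1], [1, 0], [0, 1], [0, 0], [0, 1]])
    fm = make_feature_matrix(bits, ids, bit_names=["split_bit", "noise"])
    Y = pd.DataFrame({"ep1": [1, 1, 1, 0, 0, 0], "ep2": [0, 0, 0, 1, 1, 1]},
                     index=fm.values.index, dtype=float)
    return fm, Y


class TestInduceTree:
    def test_six_compound_fixture_recovers_single_split(self):
        fm, Y = six_compound_fixture()
        tree = induce_tree(fm, Y)
        assert not tree.root.is_leaf
        assert tree.root.test.feature == "split_bit"
        leaves = tree.leaves()
        assert len(leaves) == 2
        sizes = sorted(len(l.members) for l in leaves)
        assert sizes == [3, 3]
        # matches exhaustive depth-1 enumeration
        optima, best = brute_force_root_split(
            fm.values, fm.metadata, Y.to_numpy(), min_leaf=3)
        assert ("split_bit", None) in optima
        assert best == pytest.approx(cluster_variance(Y.to_numpy()))

    def test_homogeneous_targets_single_leaf(self):
        fm, Y = six_compound_fixture()
        Y[:] = 1.0
        tree = induce_tree(fm, Y)
        assert tree.root.is_leaf
        assert len(tree.root.members) == 6

    def test_five_compounds_min_leaf_three_cannot_split(self):
        ids = [f"m{i}" for i in range(5)]
        fm = make_feature_matrix(np.array([[1], [1], [1], [0], [0]]), ids)
        Y = pd.DataFrame({"ep": [1, 1, 1, 0, 0]}, index=fm.values.index,
                         dtype=float)
        tree = induce_tree(fm, Y)
        assert tree.root.is_leaf

    def test_fewer_than_min_leaf_warns_single_leaf(self):
        ids = ["a", "b"]
        fm = make_feature_matrix(np.array([[1], [0]]), ids)
        Y = pd.DataFrame({"ep": [1.0, 0.0]}, index=fm.values.index)
        with pytest.warns(UserWarning):
            tree = induce_tree(fm, Y)
        assert tree.root.is_leaf

    def test_incomplete_targets_rejected(self):
        fm, Y = six_compound_fixture()
        Y.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            induce_tree(fm, Y)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(8)
        ids = [f"m{i}" for i in range(24)]
        fm = make_feature_matrix(rng.integers(0, 2, (24, 5)), ids,
                                 numeric={"mw": rng.uniform(50, 400, 24)})
        Y = pd.DataFrame(rng.integers(0, 2, (24, 3)).astype(float),
                         index=fm.values.index, columns=["e1", "e2", "e3"])
        t1 = induce_tree(fm, Y)
        perm = rng.permutation(24)
        from toxclust.features import FeatureMatrix
        fm2 = FeatureMatrix(values=fm.values.iloc[perm], metadata=fm.metadata)
        t2 = induce_tree(fm2, Y.iloc[perm])
        assert ({frozenset(l.members) for l in t1.leaves()}
                == {frozenset(l.members) for l in t2.leaves()})

    def test_leaves_partition_training_set(self, synth_recovery):
        import toxclust as tc
        ds = synth_recovery
        kept, _ = tc.filter_studies(ds.studies)
        mat = tc.aggregate_endpoints(kept, ds.glossary, ds.compounds)
        fm = tc.build_feature_matrix(ds.compounds)
        pot = tc.discretize(mat)
        comp, _ = tc.impute_missing(pot, fm, tc.ECCParams(seed=7))
        tree = induce_tree(fm, comp)
        members = [m for l in tree.leaves() for m in l.members]
        assert len(members) == len(ds.compounds)
        assert set(members) == set(ds.compounds["compound_id"])
        assert all(len(l.members) >= tree.params.min_leaf
                   for l in tree.leaves())

    @pytest.mark.parametrize("seed", range(8))
    def test_root_split_matches_brute_force_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 9))
        n_bits = int(rng.integers(2, 5))
        ids = [f"m{i}" for i in range(n)]
        fm = make_feature_matrix(
            rng.integers(0, 2, (n, n_bits)), ids,
            numeric={"mw": np.round(rng.uniform(50, 400, n), 1),
                     "logp": np.round(rng.uniform(-1, 5, n), 2)})
        Y = pd.DataFrame(rng.integers(0, 2, (n, 3)).astype(float),
                         index=fm.values.index, columns=["e1", "e2", "e3"])
        params = PCTParams(min_leaf=2)
        tree = induce_tree(fm, Y, params)
        optima, best = brute_force_root_split(fm.values, fm.metadata,
                                              Y.to_numpy(), params.min_leaf)
        if tree.root.is_leaf:
            # no admissible positive-reduction split, or F-test refusal
            if optima:
                pooled = cluster_variance(Y.to_numpy()) - best
                assert not f_test_accept(cluster_variance(Y.to_numpy()),
                                         max(pooled, 0.0), n,
                                         params.f_test_alpha)
        else:
            chosen = (tree.root.test.feature, tree.root.test.threshold)
            assert chosen in optima


class TestAssignAndSerialize:
    @pytest.fixture
    def fitted(self):
        fm, Y = six_compound_fixture()
        return fm, Y, induce_tree(fm, Y)

    def test_training_consistency(self, fitted):
        fm, Y, tree = fitted
        memberships = {m: l.cluster_id for l in tree.leaves()
                       for m in l.members}
        for cid in fm.values.index:
            res = assign(tree, fm.values.loc[cid])
            assert res.cluster_id == memberships[cid]

    def test_untested_features_irrelevant(self, fitted):
        fm, Y, tree = fitted
        row = fm.values.loc["m0"].copy()
        ref = assign(tree, row)
        row["noise"] = 1 - row["noise"]
        assert assign(tree, row).cluster_id == ref.cluster_id

    def test_novel_compound_routes_by_root_bit(self, fitted):
        fm, Y, tree = fitted
        yes = assign(tree, {"split_bit": 1.0, "noise": 0.0})
        no = assign(tree, {"split_bit": 0.0, "noise": 0.0})
        assert yes.cluster_id != no.cluster_id
        assert yes.prediction == {"ep1": 1, "ep2": 0}
        assert no.prediction == {"ep1": 0, "ep2": 1}
        assert yes.path == ["split_bit present"]

    def test_missing_tested_feature_named(self, fitted):
        _, _, tree = fitted
        with pytest.raises(KeyError, match="split_bit"):
            assign(tree, {"noise": 1.0})

    def test_json_roundtrip_preserves_assignments(self, fitted, tmp_path):
        fm, Y, tree = fitted
        p = tmp_path / "model.json"
        tree.to_json(p)
        back = PCTree.from_json(p)
        for cid in fm.values.index:
            assert (assign(back, fm.values.loc[cid]).cluster_id
                    == assign(tree, fm.values.loc[cid]).cluster_id)
        assert back.training_digest == tree.training_digest

    def test_dot_export(self, fitted, tmp_path):
        _, _, tree = fitted
        text = tree.to_dot(tmp_path / "t.dot")
        assert text.startswith("digraph")
        assert "split_bit" in text
        assert (tmp_path / "t.dot").exists()

    def test_manual_leaf_split_utility(self, fitted):
        fm, Y, tree = fitted
        # make one leaf heterogeneous in 'noise' and split it by hand
        leaf = tree.leaves()[0]
        target_cluster = leaf.cluster_id
        tree2 = split_leaf_by_feature(tree, target_cluster, "noise", fm, Y)
        assert len(tree2.leaves()) == 3
        members = [m for l in tree2.leaves() for m in l.members]
        assert sorted(members) == sorted(fm.values.index)
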