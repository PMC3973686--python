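"""Tree induction, split search, ensembles and MDI importance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

from ttrees import tree_core
from ttrees.tree_core import (
    Forest,
    ForestParams,
    best_split_exhaustive,
    fit_forest,
    gini_impurity,
    grow_tree,
    load_forest,
    random_cutpoint_split,
    save_forest,
)
from ttrees.evaluation import auc


# ---------------------------------------------------------------- oracles

def brute_force_best_split(values, labels):
    """Independent threshold scan: every midpoint between distinct values."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, int)
    uniq = np.unique(values)
    best = None
    n = len(values)
    n1 = labels.sum()
    i0 = gini_impurity((n - n1, n1))
    for a, b in zip(uniq[:-1], uniq[1:]):
        cut = (a + b) / 2
        left = values <= cut
        nl, cl = int(left.sum()), int(labels[left].sum())
        il = gini_impurity((nl - cl, cl))
        ir = gini_impurity((n - nl - (n1 - cl), n1 - cl))
        d = i0 - (nl / n) * il - ((n - nl) / n) * ir
        if best is None or d > best[0] + 1e-15:
            best = (d, cut)
    return best


class PyCart:
    """Reference CART-Gini (all variables, exhaustive midpoint cuts,
    ties toward lowest cut then lowest variable index)."""

    def __init__(self, X, y, n_min=2):
        self.X, self.y, self.n_min = X, y, n_min
        self.root = self._grow(np.arange(len(y)))

    def _grow(self, idx):
        y = self.y[idx]
        if y.min() == y.max() or len(idx) < max(2, self.n_min):
            return {"leaf": (int((y == 0).sum()), int((y == 1).sum()))}
        best = None
        for j in range(self.X.shape[1]):
            v = self.X[idx, j].astype(float)
            labels = y
            uniq = np.unique(v)
            n, n1 = len(v), labels.sum()
            i0 = gini_impurity((n - n1, n1))
            for a, b in zip(uniq[:-1], uniq[1:]):
                cut = (a + b) / 2
                left = v <= cut
                nl, cl = int(left.sum()), int(labels[left].sum())
                il = gini_impurity((nl - cl, cl))
                ir = gini_impurity((n - nl - (n1 - cl), n1 - cl))
                d = i0 - (nl / n) * il - ((n - nl) / n) * ir
                key = (d, -cut, -j)
                if best is None or key > best[0]:
                    best = (key, j, cut)
        if best is None:
            return {"leaf": (int((y == 0).sum()), int((y == 1).sum()))}
        _, j, cut = best
        mask = self.X[idx, j] <= cut
        return {
            "var": j,
            "cut": cut,
            "left": self._grow(idx[mask]),
            "right": self._grow(idx[~mask]),
        }


def assert_same_tree(node, tree, i=0):
    """Walk a PyCart nested dict against flat kernel arrays."""
    if "leaf" in node:
        assert tree.feat[i] == -1
        n0 = tree.n_node[i] - tree.n_case[i]
        assert (n0, tree.n_case[i]) == node["leaf"]
        return
    assert tree.feat[i] == node["var"]
    assert tree.thr[i] == pytest.approx(node["cut"])
    assert_same_tree(node["left"], tree, tree.left[i])
    assert_same_tree(node["right"], tree, tree.right[i])


# ----------------------------------------------------------------- tests

class TestGini:
    @pytest.mark.parametrize(
        "counts,expected", [((2, 2), 0.5), ((5, 0), 0.0), ((3, 1), 0.375)]
    )
    def test_values(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected)

    def test_empty_node_raises(self):
        with pytest.raises(ValueError):
            gini_impurity((0, 0))


class TestBestSplitExhaustive:
    def test_perfect_split(self):
        spec = best_split_exhaustive([0, 0, 1, 1], [0, 0, 1, 1])
        assert spec.impurity_decrease == pytest.approx(0.5)
        assert 0 < spec.cut_point < 1

    def test_constant_values_give_none(self):
        assert best_split_exhaustive([2, 2, 2], [0, 1, 0]) is None

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 50))
        values = rng.choice([0.0, 1.0, 2.0, 3.5], size=k)
        labels = rng.integers(0, 2, size=k)
        spec = best_split_exhaustive(values, labels)
        oracle = brute_force_best_split(values, labels)
        if values.min() == values.max():
            assert spec is None
        else:
            assert spec.impurity_decrease == pytest.approx(oracle[0], abs=1e-12)


class TestRandomCutpointSplit:
    def test_cut_strictly_inside_range(self, rng):
        values = np.array([0, 1, 2, 0, 2], float)
        for s in range(50):
            spec = random_cutpoint_split(values, [0, 1, 1, 0, 1], seed=s)
            assert 0 < spec.cut_point < 2
            assert 0 < (values <= spec.cut_point).sum() < len(values)

    def test_pure_labels_zero_decrease(self):
        spec = random_cutpoint_split([0, 1, 2, 2], [1, 1, 1, 1], seed=0)
        assert spec.impurity_decrease == pytest.approx(0.0)

    def test_cut_distribution_uniform(self):
        cuts = [
            random_cutpoint_split([0.0, 2.0], [0, 1], seed=s).cut_point
            for s in range(10_000)
        ]
        stat = kstest(np.asarray(cuts) / 2.0, "uniform")
        assert stat.pvalue > 0.01

    def test_constant_none(self):
        assert random_cutpoint_split([1, 1, 1], [0, 1, 0], seed=1) is None


class TestGrowTree:
    def test_pure_root_single_leaf(self):
        X = np.zeros((5, 3), dtype=np.int8)
        t = grow_tree(X, np.ones(5, np.uint8), ForestParams(T=1), seed=0)
        assert t.n_nodes == 1 and t.feat[0] == -1

    def test_xor_dataset_fully_learned(self):
        # XOR over two genotype-coded variables needs at least 3 splits
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]] * 8, dtype=np.int8)
        y = (X[:, 0] ^ X[:, 1]).astype(np.uint8)
        t = grow_tree(X, y, ForestParams(m_try=2), seed=4)
        pred = t.predict_proba(X)
        assert ((pred > 0.5).astype(int) == y).all()
        assert t.n_internal >= 3

    def test_same_seed_same_tree(self, rng):
        X = rng.integers(0, 3, size=(80, 10)).astype(np.int8)
        y = rng.integers(0, 2, 80).astype(np.uint8)
        t1 = grow_tree(X, y, ForestParams(m_try=3), seed=9)
        t2 = grow_tree(X, y, ForestParams(m_try=3), seed=9)
        np.testing.assert_array_equal(t1.feat, t2.feat)
        np.testing.assert_array_equal(t1.thr, t2.thr)

    @pytest.mark.parametrize("seed", range(8))
    def test_reproduces_reference_cart(self, seed):
        """m_try=p, exhaustive, no bootstrap == classical CART-Gini."""
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 3, size=(40, 4)).astype(np.int8)
        y = rng.integers(0, 2, 40).astype(np.uint8)
        t = grow_tree(X, y, ForestParams(m_try=4, N_min=5), seed=seed)
        oracle = PyCart(X, y, n_min=5)
        assert_same_tree(oracle.root, t)

    def test_accepted_splits_partition_parent(self, rng):
        X = rng.integers(0, 3, size=(120, 6)).astype(np.int8)
        y = rng.integers(0, 2, 120).astype(np.uint8)
        t = grow_tree(X, y, ForestParams(m_try=2), seed=2)
        for i in np.nonzero(t.feat >= 0)[0]:
            assert t.delta[i] >= 0
            assert t.n_node[t.left[i]] + t.n_node[t.right[i]] == t.n_node[i]
            assert t.n_node[t.left[i]] > 0 and t.n_node[t.right[i]] > 0


class TestForest:
    def test_soft_vote_average(self, small_dataset):
        f = fit_forest(small_dataset, params=ForestParams(T=2, seed=1))
        p1 = f.trees[0].predict_proba(small_dataset.genotypes)
        p2 = f.trees[1].predict_proba(small_dataset.genotypes)
        np.testing.assert_allclose(
            f.predict_proba(small_dataset.genotypes), (p1 + p2) / 2
        )

    def test_training_auc_on_separable_data(self, rng):
        n = 100
        X = rng.integers(0, 3, size=(n, 10)).astype(np.int8)
        y = (X[:, 0] >= 1).astype(np.uint8)
        f = fit_forest(X, y, ForestParams(T=100, seed=0))
        assert auc(f.predict_proba(X), y) == pytest.approx(1.0)

    def test_mdi_single_informative_variable(self, rng):
        X = rng.integers(0, 3, size=(200, 6)).astype(np.int8)
        y = (X[:, 3] >= 1).astype(np.uint8)
        f = fit_forest(X, y, ForestParams(T=30, m_try=6, seed=0))
        imp = f.mdi_importance()
        assert imp.argmax() == 3

    def test_mdi_conservation_per_tree(self, small_dataset):
        f = fit_forest(small_dataset, params=ForestParams(T=10, seed=5))
        for t in f.trees:
            np.testing.assert_allclose(
                t.mdi_importance(small_dataset.n_snps).sum(),
                t.total_weighted_decrease(),
                atol=1e-10,
            )

    def test_noise_importances_spread_evenly(self, rng):
        X = rng.integers(0, 3, size=(300, 8)).astype(np.int8)
        y = rng.integers(0, 2, 300).astype(np.uint8)  # pure noise
        f = fit_forest(X, y, ForestParams(T=100, seed=3))
        imp = f.mdi_importance()
        assert imp.min() > 0
        assert imp.max() / imp.min() < 3.0

    def test_serialization_roundtrip(self, tmp_path, small_dataset):
        f = fit_forest(small_dataset, params=ForestParams(T=5, seed=2))
        save_forest(f, tmp_path / "m.jsonl")
        back = load_forest(tmp_path / "m.jsonl")
        np.testing.assert_array_equal(
            back.predict_proba(small_dataset.genotypes),
            f.predict_proba(small_dataset.genotypes),
        )

    def test_missing_values_rejected(self, small_dataset):
        G = small_dataset.genotypes.copy()
        G[0, 0] = -1
        with pytest.raises(ValueError, match="impute"):
            fit_forest(G, small_dataset.phenotype, ForestParams(T=1))
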