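"""Inner trees, outer splits, T-Tree ensembles and nested importances."""

import numpy as np
import pytest

from ttrees import ttree
from ttrees.evaluation import auc
from ttrees.genotype_data import BlockMap, GenotypeDataset, make_block_map
from ttrees.ttree import (
    TTreeParams,
    fit_ttrees,
    grow_inner_tree,
    inner_tree_scores,
    load_ttrees,
    merge_important_snps,
    save_ttrees,
    split_outer_node,
)


def walk_inner(tree, x):
    """Brute-force per-sample walk of an inner tree (reference route)."""
    t = 0
    while tree.var[t] >= 0:
        t = tree.left[t] if x[tree.var[t]] <= tree.cut[t] else tree.right[t]
    return tree.leaf_proba()[t]


def make_block_data(rng, n=200, B=10):
    X = rng.integers(0, 3, size=(n, B)).astype(np.int8)
    y = (X[:, 2] + X[:, 5] >= 2).astype(np.uint8)
    return X, y


class TestInnerTree:
    def test_ic1_is_a_stump(self, rng):
        X, y = make_block_data(rng)
        t = grow_inner_tree(X, y, IC=1, k_internal=3, seed=0)
        assert t.n_test_nodes == 1
        assert t.n_nodes == 3
        assert t.var[0] >= 0 and t.var[1] == -1 and t.var[2] == -1

    def test_pure_labels_yield_stump_probability(self, rng):
        X = rng.integers(0, 3, size=(30, 5)).astype(np.int8)
        t = grow_inner_tree(X, np.ones(30, np.uint8), IC=4, seed=1)
        assert t.n_test_nodes == 0
        assert t.leaf_proba()[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("ic", [1, 3, 5])
    def test_node_count_bound(self, rng, ic):
        for s in range(100):
            X, y = make_block_data(rng, n=60)
            t = grow_inner_tree(X, y, IC=ic, k_internal=4, seed=s)
            assert t.n_test_nodes <= ic
            assert (t.var < X.shape[1]).all()

    def test_scores_match_reference_walk(self, rng):
        X, y = make_block_data(rng, n=150)
        t = grow_inner_tree(X, y, IC=5, k_internal=4, seed=3)
        scores = inner_tree_scores(t, X)
        expected = np.array([walk_inner(t, x) for x in X])
        np.testing.assert_allclose(scores, expected)

    def test_leaf_probabilities_are_case_fractions(self, rng):
        X, y = make_block_data(rng, n=150)
        t = grow_inner_tree(X, y, IC=5, seed=7)
        scores = inner_tree_scores(t, X)
        for val in np.unique(scores):
            members = scores == val
            assert y[members].mean() == pytest.approx(val)

    def test_stump_example_scores(self):
        # stump on SNP 0 at cut 0.5 with leaf probs 0.1 / 0.9
        t = ttree.InnerTree(
            0,
            var=np.array([0, -1, -1]),
            cut=np.array([0.5, 0.0, 0.0]),
            left=np.array([1, -1, -1]),
            right=np.array([2, -1, -1]),
            n_node=np.array([20, 10, 10]),
            n_case=np.array([10, 1, 9]),
            delta=np.zeros(3),
            n_test_nodes=1,
        )
        X = np.array([[0], [2]], dtype=np.int8)
        np.testing.assert_allclose(t.scores(X), [0.1, 0.9])


class TestOuterSplit:
    def test_perfectly_separating_block(self, rng):
        # block 0 contains a perfect separator; IC=1 finds it
        n = 100
        X = rng.integers(0, 3, size=(n, 4)).astype(np.int8)
        y = (X[:, 1] >= 1).astype(np.uint8)
        data = GenotypeDataset(X, y, [f"s{i}" for i in range(4)])
        bm = BlockMap(blocks=(np.arange(4),), block_size_B=4)
        params = TTreeParams(T=1, IC=1, k_internal=4, m_try_blocks=1)
        best = None
        for seed in range(20):  # ET cut-point is random; try several draws
            s = split_outer_node(np.arange(n), data, bm, params, seed=seed)
            if s and (best is None or s.impurity_decrease > best.impurity_decrease):
                best = s
        n1 = int(y.sum())
        i_root = 2 * (n1 / n) * (1 - n1 / n)
        assert best.impurity_decrease == pytest.approx(i_root)

    def test_constant_scores_give_none(self):
        X = np.zeros((30, 6), dtype=np.int8)
        y = np.arange(30) % 2
        data = GenotypeDataset(X, y, [f"s{i}" for i in range(6)])
        bm = make_block_map(6, 3)
        s = split_outer_node(np.arange(30), data, bm,
                             TTreeParams(T=1, IC=2, m_try_blocks=2), seed=0)
        assert s is None

    @pytest.mark.parametrize("seed", range(25))
    def test_b1_ic1_reduces_to_univariate_threshold(self, seed):
        """With B=1 and IC=1 the induced partition must equal a
        threshold split on that single SNP."""
        rng = np.random.default_rng(seed)
        n = 60
        X = rng.integers(0, 3, size=(n, 8)).astype(np.int8)
        y = rng.integers(0, 2, n).astype(np.uint8)
        data = GenotypeDataset(X, y, [f"s{i}" for i in range(8)])
        bm = make_block_map(8, 1)
        s = split_outer_node(np.arange(n), data, bm,
                             TTreeParams(T=1, IC=1, k_internal=1,
                                         m_try_blocks=3), seed=seed)
        if s is None:
            return
        mask = s.left_mask(data.genotypes)
        g = X[:, s.block_index]
        candidates = [g <= t for t in (0.5, 1.5)]
        assert any(
            np.array_equal(mask, c) or np.array_equal(mask, ~c)
            for c in candidates
        )


class TestEnsemble:
    def test_training_auc_separable(self, rng):
        n = 120
        X = rng.integers(0, 3, size=(n, 20)).astype(np.int8)
        y = (X[:, 4] >= 1).astype(np.uint8)
        data = GenotypeDataset(X, y, [f"s{i}" for i in range(20)])
        m = fit_ttrees(data, make_block_map(20, 5),
                       TTreeParams(T=50, IC=2, N_min=10, seed=0))
        assert auc(m.predict_proba(X), y) > 0.99

    def test_same_seed_byte_identical_model(self, tmp_path, rng):
        n = 80
        X = rng.integers(0, 3, size=(n, 12)).astype(np.int8)
        y = rng.integers(0, 2, n).astype(np.uint8)
        data = GenotypeDataset(X, y, [f"s{i}" for i in range(12)])
        for i in (1, 2):
            m = fit_ttrees(data, make_block_map(12, 4),
                           TTreeParams(T=5, IC=2, N_min=10, seed=42))
            save_ttrees(m, tmp_path / f"m{i}.jsonl")
        assert (tmp_path / "m1.jsonl").read_bytes() == (
            tmp_path / "m2.jsonl"
        ).read_bytes()

    def test_serialization_roundtrip_predictions(self, tmp_path, rng):
        n = 80
        X = rng.integers(0, 3, size=(n, 12)).astype(np.int8)
        y = (X[:, 1] >= 1).astype(np.uint8)
        data = GenotypeDataset(X, y, [f"s{i}" for i in range(12)])
        m = fit_ttrees(data, make_block_map(12, 4),
                       TTreeParams(T=8, IC=3, N_min=10, seed=3))
        save_ttrees(m, tmp_path / "m.jsonl")
        back = load_ttrees(tmp_path / "m.jsonl")
        np.testing.assert_allclose(back.predict_proba(X), m.predict_proba(X))

    def test_block_containment(self, rng):
        n = 150
        X = rng.integers(0, 3, size=(n, 30)).astype(np.int8)
        y = (X[:, 7] + X[:, 8] >= 2).astype(np.uint8)
        data = GenotypeDataset(X, y, [f"s{i}" for i in range(30)])
        bm = make_block_map(30, 6)
        m = fit_ttrees(data, bm, TTreeParams(T=10, IC=4, N_min=20, seed=1))
        for t in m.trees:
            for it in t.inner_trees():
                block_snps = set(bm.blocks[it.block_index].tolist())
                used = set(it.var[it.var >= 0].tolist())
                assert used <= block_snps


class TestImportances:
    @pytest.fixture()
    def fitted(self, rng):
        n = 200
        X = rng.integers(0, 3, size=(n, 24)).astype(np.int8)
        y = ((X[:, 9] >= 1) & (X[:, 10] >= 1)).astype(np.uint8)
        data = GenotypeDataset(X, y, [f"s{i}" for i in range(24)])
        bm = make_block_map(24, 6)
        m = fit_ttrees(data, bm, TTreeParams(T=40, IC=4, N_min=30, seed=2))
        return m

    def test_causal_block_dominates(self, fitted):
        bi = fitted.block_importance()
        assert bi.argmax() == 1  # SNPs 9, 10 live in block 1 (6..11)

    def test_snp_conservation_per_inner_tree(self, fitted):
        for t in fitted.trees:
            for it in t.inner_trees():
                contrib = (
                    (it.n_node[it.var >= 0] / t.n_in_bag)
                    * it.delta[it.var >= 0]
                ).sum()
                assert contrib == pytest.approx(
                    it.total_weighted_decrease(t.n_in_bag), abs=1e-10
                )

    def test_block_conservation_per_tree(self, fitted):
        nb = fitted.block_map.n_blocks
        for t in fitted.trees:
            outer = t.oblk >= 0
            total = ((t.onn[outer] / t.n_in_bag) * t.odelta[outer]).sum()
            assert t.block_importance(nb).sum() == pytest.approx(total, abs=1e-10)

    def test_ensemble_importance_is_tree_average(self, fitted):
        p = fitted.n_features
        per_tree = np.mean([t.snp_importance(p) for t in fitted.trees], axis=0)
        np.testing.assert_allclose(fitted.snp_importance(), per_tree)


class TestRegionReport:
    def test_gap_zero_one_region_per_snp(self):
        imp = np.zeros(50)
        imp[[3, 10, 30]] = [1.0, 2.0, 3.0]
        regions = merge_important_snps(imp, top_n=3, gap=0)
        assert len(regions) == 3

    def test_nearby_snps_merge(self):
        imp = np.zeros(100)
        imp[[5, 12, 18]] = [1.0, 3.0, 2.0]  # within 20 of each other
        imp[80] = 5.0
        regions = merge_important_snps(imp, top_n=4, gap=20)
        assert len(regions) == 2
        first = regions[0]
        assert (first["start"], first["end"]) == (5, 18)
        assert first["top_snp"] == 12 and first["rank"] == 2
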