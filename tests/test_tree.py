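"""Tree growth, prediction, and serialization."""

import numpy as np
import pytest

from moctree import (
    Criterion,
    ObservationalDataset,
    TreeConfig,
    deserialize,
    enumerate_candidate_splits,
    estimate_node_cate,
    grow_tree,
    predict_cate,
    rmse,
    serialize,
)
from moctree.data_model import DatasetError
from tests.conftest import make_separable


def small_config(**kw) -> TreeConfig:
    base = dict(criterion="mo", max_splits=3, min_leaf=10, min_arm=2, seed=0)
    base.update(kw)
    return TreeConfig(**base)


class TestEnumeration:
    def test_constant_features_give_no_candidates(self):
        ds = ObservationalDataset(
            np.ones((6, 2)), np.arange(6.0), [1, 0, 1, 0, 1, 0]
        )
        assert enumerate_candidate_splits(ds, range(6), small_config(min_leaf=1, min_arm=1)) == []

    def test_midpoint_thresholds(self):
        ds = ObservationalDataset(
            np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]]),
            np.arange(6.0),
            [1, 1, 1, 0, 0, 0],
        )
        cands = enumerate_candidate_splits(ds, range(6), small_config(min_leaf=1, min_arm=1))
        assert [c.threshold for c in cands] == [1.5, 2.5]

    def test_children_partition_and_keep_both_arms(self):
        rng = np.random.default_rng(20)
        ds = ObservationalDataset(
            rng.standard_normal((40, 2)),
            rng.standard_normal(40),
            (rng.random(40) < 0.5).astype(int),
        )
        cfg = small_config(min_leaf=5, min_arm=2)
        for cand in enumerate_candidate_splits(ds, range(40), cfg):
            left, right = cand.left_rows, cand.right_rows
            assert np.intersect1d(left, right).size == 0
            assert np.array_equal(np.sort(np.concatenate([left, right])), np.arange(40))
            for rows in (left, right):
                w = np.asarray(ds.treatment)[rows]
                assert rows.size >= 5 and w.sum() >= 2 and (1 - w).sum() >= 2

    def test_min_arm_rule_filters_small_fixture(self):
        # 6 rows cannot give 2 of each arm per child -> no candidates at all
        ds6 = ObservationalDataset(
            np.arange(1.0, 7.0).reshape(6, 1), np.zeros(6), [1, 0, 1, 0, 1, 0]
        )
        cfg = small_config(min_leaf=1, min_arm=2)
        assert enumerate_candidate_splits(ds6, range(6), cfg) == []
        # 8 alternating rows: only the middle threshold keeps 2 per arm per child
        ds8 = ObservationalDataset(
            np.arange(1.0, 9.0).reshape(8, 1), np.zeros(8), [1, 0, 1, 0, 1, 0, 1, 0]
        )
        cands = enumerate_candidate_splits(ds8, range(8), cfg)
        assert [c.threshold for c in cands] == [4.5]
        for c in cands:
            for rows in (c.left_rows, c.right_rows):
                w = np.asarray(ds8.treatment)[rows]
                assert w.sum() >= 2 and (1 - w).sum() >= 2


class TestGrowth:
    def test_zero_splits_yields_root_ate(self, separable_ds):
        model = grow_tree(separable_ds, small_config(max_splits=0))
        assert model.n_splits == 0
        expected = estimate_node_cate(separable_ds, range(separable_ds.n))
        pred = predict_cate(model, separable_ds.covariates)
        assert np.allclose(pred, expected)

    @pytest.mark.parametrize("criterion", ["mh", "mo", "ct"])
    def test_first_split_recovers_separable_effect(self, separable_ds, criterion):
        model = grow_tree(separable_ds, small_config(criterion=criterion, max_splits=1))
        x1 = separable_ds.covariates[:, 0]
        gap_lo = x1[x1 <= 0].max()
        gap_hi = x1[x1 > 0].min()
        assert model.root.feature_index == 0
        assert gap_lo < model.root.threshold < gap_hi

    def test_two_leaf_predictions_on_separable_fixture(self, separable_ds):
        model = grow_tree(separable_ds, small_config(criterion="mo", max_splits=1))
        # noiseless: treated-minus-control difference is exactly ±2
        pred = predict_cate(model, np.array([[2.0, 0.0], [-2.0, 0.0]]))
        assert pred[0] == pytest.approx(2.0)
        assert pred[1] == pytest.approx(-2.0)

    def test_split_budget_respected(self, separable_ds):
        for k in (0, 1, 2, 5):
            model = grow_tree(separable_ds, small_config(max_splits=k))
            assert model.n_splits <= k

    def test_leaf_counts_partition_training_rows(self, separable_ds):
        model = grow_tree(separable_ds, small_config(max_splits=5))
        leaves = []

        def collect(node):
            if node.is_leaf:
                leaves.append(node)
            else:
                collect(node.left)
                collect(node.right)

        collect(model.root)
        assert sum(leaf.n for leaf in leaves) == separable_ds.n
        assert all(leaf.n_treated + leaf.n_control == leaf.n for leaf in leaves)

    def test_training_rmse_nonincreasing_in_splits(self):
        ds = make_separable(n=600, seed=21)
        truth = 2.0 * np.where(ds.covariates[:, 0] > 0, 1.0, -1.0)
        errs = []
        for k in (0, 1, 2, 4):
            model = grow_tree(ds, small_config(criterion="ct", max_splits=k))
            errs.append(rmse(predict_cate(model, ds.covariates), truth))
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_ct_equals_mo_max_fit_when_archive_singleton(self):
        # a single valid candidate -> every archive is a singleton
        ds = ObservationalDataset(
            np.repeat([[0.0], [1.0]], 10, axis=0),
            np.r_[np.zeros(10), np.ones(10)],
            [1, 0] * 10,
        )
        cfg_ct = small_config(criterion="ct", max_splits=1, min_leaf=2)
        cfg_mo = small_config(
            criterion="mo", selection_rule="max_fit", max_splits=1, min_leaf=2
        )
        t_ct = grow_tree(ds, cfg_ct)
        t_mo = grow_tree(ds, cfg_mo)
        assert t_mo.root.archive_size == 1
        assert t_ct.root.feature_index == t_mo.root.feature_index
        assert t_ct.root.threshold == t_mo.root.threshold
        assert t_ct.root.left.tau_hat == t_mo.root.left.tau_hat
        assert t_ct.root.right.tau_hat == t_mo.root.right.tau_hat

    def test_honest_mode_reestimates_leaves(self):
        rng = np.random.default_rng(22)
        n = 400
        X = rng.standard_normal((n, 2))
        w = (rng.random(n) < 0.5).astype(int)
        y = (2 * w - 1) * np.where(X[:, 0] > 0, 1.0, -1.0) + 0.1 * rng.standard_normal(n)
        ds = ObservationalDataset(X, y, w, propensity=np.full(n, 0.5))
        model = grow_tree(ds, small_config(criterion="mo", max_splits=1, honest=True, seed=5))
        leaves = [model.root.left, model.root.right]
        assert sum(leaf.n for leaf in leaves) == n - n // 2  # estimation half
        pred = predict_cate(model, np.array([[3.0, 0.0], [-3.0, 0.0]]))
        assert pred[0] > 0 > pred[1]

    def test_negative_max_splits_rejected(self):
        with pytest.raises(ValueError):
            TreeConfig(max_splits=-1)


class TestPredict:
    def test_dimension_mismatch(self, separable_ds):
        model = grow_tree(separable_ds, small_config(max_splits=1))
        with pytest.raises(DatasetError):
            predict_cate(model, np.zeros((3, 5)))

    def test_training_rows_route_to_their_leaf_estimates(self, separable_ds):
        model = grow_tree(separable_ds, small_config(max_splits=4))
        pred = predict_cate(model, separable_ds.covariates)
        leaves = {}

        def collect(node, rows):
            if node.is_leaf:
                leaves[id(node)] = (node, rows)
                return
            mask = separable_ds.covariates[rows, node.feature_index] <= node.threshold
            collect(node.left, rows[mask])
            collect(node.right, rows[~mask])

        collect(model.root, np.arange(separable_ds.n))
        for node, rows in leaves.values():
            assert np.allclose(pred[rows], node.tau_hat)


class TestSerialization:
    def test_round_trip_zero_split_model(self, separable_ds):
        model = grow_tree(separable_ds, small_config(max_splits=0))
        clone = deserialize(serialize(model))
        X = separable_ds.covariates
        assert np.array_equal(predict_cate(clone, X), predict_cate(model, X))

    def test_round_trip_deep_model_on_random_rows(self):
        rng = np.random.default_rng(23)
        ds = make_separable(n=2000, seed=24)
        model = grow_tree(ds, small_config(max_splits=15, min_leaf=10))
        clone = deserialize(serialize(model))
        X = rng.standard_normal((1000, 2)) * 2
        assert np.array_equal(predict_cate(clone, X), predict_cate(model, X))
        assert serialize(clone) == serialize(model)

    def test_determinism_byte_for_byte(self, separable_ds):
        cfg = small_config(criterion="mo", max_splits=4)
        s1 = serialize(grow_tree(separable_ds, cfg))
        s2 = serialize(grow_tree(separable_ds, cfg))
        assert s1 == s2

    def test_tampered_document_rejected(self, separable_ds):
        import json

        model = grow_tree(separable_ds, small_config(max_splits=1))
        doc = json.loads(serialize(model))
        del doc["root"]["left"]
        with pytest.raises(ValueError, match="malformed|missing"):
            deserialize(json.dumps(doc))

    def test_wrong_format_rejected(self):
        with pytest.raises(ValueError):
            deserialize('{"format": "something-else", "version": 1}')
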