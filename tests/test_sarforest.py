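"""Entropy filtering and the descriptor-disjoint five-tree decision forest."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cypcons import sarforest, synthdata


def _separable(rng, n=120, n_desc=20, n_inf=5, shift=2.5):
    y = np.array(["P"] * (n // 3) + ["W"] * (n - n // 3))
    X = pd.DataFrame(
        rng.normal(size=(n, n_desc)),
        columns=[f"d{i}" for i in range(n_desc)],
        index=[f"c{i}" for i in range(n)],
    )
    for i in range(n_inf):
        X[f"d{i}"] += np.where(y == "P", shift, 0.0)
    return X, y


class TestShannonEntropy:
    def test_constant_column(self):
        assert sarforest.shannon_entropy([3.0] * 10) == 0.0

    def test_two_equal_values(self):
        assert sarforest.shannon_entropy([0, 1] * 8) == pytest.approx(1.0)

    def test_uniform_eight_levels(self):
        col = list(range(8)) * 4
        assert sarforest.shannon_entropy(col) == pytest.approx(3.0)

    def test_continuous_discretized_to_ten_bins(self, rng):
        col = rng.random(10000)
        assert sarforest.shannon_entropy(col) == pytest.approx(np.log2(10), abs=0.01)


class TestFilterDescriptors:
    def test_constant_columns_always_removed(self, rng):
        df = pd.DataFrame({"flat": np.ones(50), "ok": rng.normal(size=50)})
        kept = sarforest.filter_descriptors(df, min_entropy=0.5)
        assert list(kept.columns) == ["ok"]

    def test_synthetic_table_passes_327(self, study):
        kept = sarforest.filter_descriptors(study.train_descriptors)
        assert kept.shape[1] == 327

    def test_zero_threshold_keeps_all(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
        assert sarforest.filter_descriptors(df, min_entropy=0.0).shape[1] == 5

    def test_all_removed_is_error(self):
        df = pd.DataFrame({"a": np.ones(10)})
        with pytest.raises(ValueError):
            sarforest.filter_descriptors(df, min_entropy=0.5)


class TestBuildTree:
    def test_pure_node_is_leaf(self):
        X = pd.DataFrame({"d": [1.0, 2.0, 3.0, 4.0, 5.0] * 2})
        tree = sarforest.build_tree(X, ["P"] * 10)
        assert tree.is_leaf and tree.n_weak == 0

    def test_perfect_descriptor_gives_depth_one(self):
        X = pd.DataFrame({"d": np.r_[np.zeros(10), np.ones(10)]})
        y = ["W"] * 10 + ["P"] * 10
        tree = sarforest.build_tree(X, y)
        assert tree.descriptor == "d"
        assert tree.left.is_leaf and tree.right.is_leaf
        preds = [tree.predict_row(row) for _, row in X.iterrows()]
        assert np.mean((np.array(preds) >= 0.5) == (np.array(y) == "P")) == 1.0

    def test_first_split_matches_brute_force(self, rng):
        # 12 compounds x 3 descriptors: exhaustive oracle over all splits
        X = pd.DataFrame(rng.normal(size=(12, 3)), columns=list("abc"), index=range(12))
        y = np.where(rng.random(12) < 0.5, "P", "W")
        if len(set(y)) < 2:
            y[0] = "P" if y[0] == "W" else "W"
        tree = sarforest.build_tree(X, y, min_leaf=1)

        def gini(labels):
            if len(labels) == 0:
                return 0.0
            p = np.mean(labels == "P")
            return 2 * p * (1 - p)

        best = None
        yarr = np.asarray(y)
        for col in X.columns:
            vals = np.sort(X[col].unique())
            for lo, hi in zip(vals[:-1], vals[1:]):
                thr = (lo + hi) / 2
                mask = X[col] <= thr
                dec = gini(yarr) - (mask.sum() * gini(yarr[mask]) + (~mask).sum() * gini(yarr[~mask])) / 12
                if best is None or dec > best[0] + 1e-15:
                    best = (dec, col, thr)
        assert tree.descriptor == best[1]
        assert tree.threshold == pytest.approx(best[2])
        assert tree.gini_decrease == pytest.approx(best[0])

    def test_gini_decrease_non_negative_everywhere(self, rng):
        X, y = _separable(rng)
        tree = sarforest.build_tree(X, y)
        stack = [tree]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                assert node.gini_decrease > 0
                stack += [node.left, node.right]

    def test_min_leaf_respected(self, rng):
        X, y = _separable(rng)
        tree = sarforest.build_tree(X, y, min_leaf=5)
        stack = [tree]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                assert node.n_potent + node.n_weak >= 5
            else:
                stack += [node.left, node.right]


class TestForest:
    def test_training_accuracy_on_separable_data(self):
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, y = _separable(rng)
            model = sarforest.train_forest(X, y)
            accs.append(np.mean(model.predict(X).to_numpy() == y))
        assert np.mean(accs) >= 0.95

    def test_descriptor_sets_pairwise_disjoint(self, rng):
        X, y = _separable(rng)
        model = sarforest.train_forest(X, y)
        for a, b in itertools.combinations(model.descriptor_sets, 2):
            assert not (a & b)

    def test_exactly_five_trees_when_possible(self, study):
        kept = sarforest.filter_descriptors(study.train_descriptors)
        model = sarforest.train_forest(kept, study.labels("train"))
        assert len(model.trees) == 5

    def test_prediction_invariant_to_tree_order(self, rng):
        X, y = _separable(rng)
        model = sarforest.train_forest(X, y)
        rev = sarforest.ForestModel(trees=model.trees[::-1], descriptor_sets=model.descriptor_sets[::-1])
        assert np.allclose(model.predict_proba(X), rev.predict_proba(X))

    def test_shuffled_labels_hurt_held_out_accuracy(self):
        rng = np.random.default_rng(17)
        X, y = _separable(rng, n=240)
        idx_tr, idx_te = np.arange(160), np.arange(160, 240)
        good = sarforest.train_forest(X.iloc[idx_tr], y[idx_tr])
        acc_good = np.mean(good.predict(X.iloc[idx_te]).to_numpy() == y[idx_te])
        y_shuf = rng.permutation(y[idx_tr])
        bad = sarforest.train_forest(X.iloc[idx_tr], y_shuf)
        acc_bad = np.mean(bad.predict(X.iloc[idx_te]).to_numpy() == y[idx_te])
        assert acc_good > acc_bad

    def test_descriptors_per_tree_order_of_magnitude(self, study):
        kept = sarforest.filter_descriptors(study.train_descriptors)
        model = sarforest.train_forest(kept, study.labels("train"))
        mean_per_tree = np.mean([len(s) for s in model.descriptor_sets])
        assert 1 <= mean_per_tree <= 12

    def test_model_json_round_trip(self, tmp_path, rng):
        X, y = _separable(rng)
        model = sarforest.train_forest(X, y)
        model.to_json(tmp_path / "f.json")
        back = sarforest.ForestModel.from_json(tmp_path / "f.json")
        assert np.allclose(model.predict_proba(X), back.predict_proba(X))


class TestUsageTally:
    def test_single_model_counts_binary(self, rng):
        X, y = _separable(rng)
        model = sarforest.train_forest(X, y)
        tally = sarforest.usage_tally([model])
        assert set(tally.values()) <= {1}

    def test_unused_descriptor_absent(self, rng):
        X, y = _separable(rng)
        model = sarforest.train_forest(X, y)
        used = set().union(*model.descriptor_sets)
        tally = sarforest.usage_tally([model])
        for d in X.columns:
            assert (d in tally) == (d in used)

    def test_accumulates_across_models(self, rng):
        X, y = _separable(rng)
        model = sarforest.train_forest(X, y)
        tally = sarforest.usage_tally([model] * 100)
        assert max(tally.values()) == 100  # one tree per model uses it, 100 models

    def test_empty_model_list_rejected(self):
        with pytest.raises(ValueError):
            sarforest.usage_tally([])
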