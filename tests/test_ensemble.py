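import itertools

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from lncda import (DNNClassifier, GradientBoostingTrees, SoftVotingClassifier,
                   build_pair_features, leaf_weight_and_gain, soft_vote)
from lncda.encoder import EncoderState
from lncda.ensemble import _RegressionTree, _TreeNode


def _state(X_c, X_d):
    return EncoderState([], [], np.asarray(X_c, float), np.asarray(X_d, float),
                        np.asarray(X_c, float).T @ np.asarray(X_d, float))


def _blobs(rng, n=60, gap=4.0):
    """Linearly separable 2-D fixture."""
    X = np.vstack([rng.standard_normal((n // 2, 2)) - gap / 2,
                   rng.standard_normal((n // 2, 2)) + gap / 2])
    y = np.repeat([0, 1], n // 2)
    return X, y


# ---------------------------------------------------------------------------
# pair features
# ---------------------------------------------------------------------------

class TestBuildPairFeatures:
    def test_concatenation(self):
        st = _state([[1.0], [2.0]], [[3.0], [4.0]])  # F=2, n=1, m=1
        t = build_pair_features(st, [(0, 0)])
        assert t.X.tolist() == [[1.0, 2.0, 3.0, 4.0]]

    def test_duplicate_pairs_identical_rows(self, rng):
        st = _state(rng.standard_normal((3, 4)), rng.standard_normal((3, 5)))
        t = build_pair_features(st, [(1, 2), (1, 2)])
        assert np.array_equal(t.X[0], t.X[1])

    def test_all_pairs_cardinality(self, rng):
        st = _state(rng.standard_normal((2, 4)), rng.standard_normal((2, 5)))
        pairs = [(i, j) for i in range(4) for j in range(5)]
        assert build_pair_features(st, pairs).X.shape == (20, 4)

    def test_out_of_range_rejected(self, rng):
        st = _state(rng.standard_normal((2, 4)), rng.standard_normal((2, 5)))
        with pytest.raises(IndexError):
            build_pair_features(st, [(4, 0)])


# ---------------------------------------------------------------------------
# feed-forward network
# ---------------------------------------------------------------------------

class TestDNN:
    def test_zero_weights_output_half(self, rng):
        model = DNNClassifier.from_weights(
            [np.zeros((3, 4)), np.zeros((4, 1))], [np.zeros(4), np.zeros(1)])
        p = model.predict_proba(rng.standard_normal((5, 3)))[:, 1]
        assert np.allclose(p, 0.5)

    def test_hand_set_single_unit(self):
        # x=1, w=1, b=0 through ReLU then logistic: sigma(1) ~ 0.7311
        model = DNNClassifier.from_weights(
            [np.array([[1.0]]), np.array([[1.0]])], [np.zeros(1), np.zeros(1)])
        p = model.predict_proba(np.array([[1.0]]))[0, 1]
        assert p == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-9)

    def test_separable_fixture_perfect_accuracy(self, rng):
        X, y = _blobs(rng)
        model = DNNClassifier(hidden_layer_sizes=(16,), epochs=500,
                              learning_rate=1e-2, seed=0).fit(X, y)
        assert (model.predict(X) == y).all()

    def test_same_seed_identical_weights(self, rng):
        X, y = _blobs(rng)
        m1 = DNNClassifier(hidden_layer_sizes=(8,), epochs=50, seed=4).fit(X, y)
        m2 = DNNClassifier(hidden_layer_sizes=(8,), epochs=50, seed=4).fit(X, y)
        for w1, w2 in zip(m1.weights_, m2.weights_):
            assert np.array_equal(w1, w2)

    def test_probabilities_strictly_inside_unit_interval(self, rng):
        X, y = _blobs(rng, n=20)
        model = DNNClassifier(hidden_layer_sizes=(8,), epochs=20, seed=1).fit(X, y)
        p = model.predict_proba(rng.standard_normal((40, 2)))[:, 1]
        assert ((p > 0) & (p < 1)).all()

    def test_duplicated_rows_equal_scores(self, rng):
        X, y = _blobs(rng, n=20)
        model = DNNClassifier(hidden_layer_sizes=(8,), epochs=20, seed=1).fit(X, y)
        row = rng.standard_normal((1, 2))
        p = model.predict_proba(np.vstack([row, row]))[:, 1]
        assert p[0] == p[1]

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            DNNClassifier().fit(rng.standard_normal((5, 2)), np.ones(5))

    def test_feature_mismatch_rejected(self, rng):
        X, y = _blobs(rng, n=20)
        model = DNNClassifier(hidden_layer_sizes=(4,), epochs=5, seed=0).fit(X, y)
        with pytest.raises(ValueError):
            model.predict_proba(rng.standard_normal((3, 5)))


# ---------------------------------------------------------------------------
# boosting mathematics
# ---------------------------------------------------------------------------

class TestLeafWeightAndGain:
    def test_leaf_weight_substitution(self):
        w, _ = leaf_weight_and_gain([1.0, 1.0], [1.0, 1.0], 0.0)
        assert w == pytest.approx(-1.0)

    def test_split_gain_substitution(self):
        # separating g=[+1,+1] from g=[-1,-1] with unit hessians, lambda 0:
        # 1/2 [4/2 + 4/2 - 0/4] = 2
        _, gain = leaf_weight_and_gain([1, 1, -1, -1], [1, 1, 1, 1], 0.0,
                                       left_mask=[True, True, False, False])
        assert gain == pytest.approx(2.0)

    def test_infinite_regularization_limit(self):
        w, gain = leaf_weight_and_gain([1, -2], [1, 1], 1e12,
                                       left_mask=[True, False])
        assert abs(w) < 1e-9 and abs(gain) < 1e-9

    def test_division_guard(self):
        with pytest.raises(ZeroDivisionError):
            leaf_weight_and_gain([1.0], [0.0], 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_tree_split_matches_exhaustive_scan(self, seed):
        """The greedy split equals a brute-force scan of every partition
        induced by every feature threshold on small fixtures."""
        rng = np.random.default_rng(seed)
        n = 20
        X = rng.standard_normal((n, 3))
        g = rng.standard_normal(n)
        h = rng.random(n) + 0.1
        lam = 0.5
        idx = np.arange(n)
        gain, f, thr, left = _RegressionTree._best_split(X, g, h, idx, lam)
        # oracle: try every (feature, midpoint) partition
        best = 0.0
        for fo in range(3):
            vals = np.unique(X[:, fo])
            for a, b in zip(vals[:-1], vals[1:]):
                cut = (a + b) / 2
                mask = X[:, fo] <= cut
                _, go = leaf_weight_and_gain(g, h, lam, left_mask=mask)
                best = max(best, go)
        assert gain == pytest.approx(best, abs=1e-9)
        if f >= 0:
            mask = X[:, f] <= thr
            _, check = leaf_weight_and_gain(g, h, lam, left_mask=mask)
            assert check == pytest.approx(gain, abs=1e-9)


class TestGradientBoosting:
    def test_single_leaf_is_newton_intercept_step(self, rng):
        y = (rng.random(30) < 0.7).astype(float)
        X = rng.standard_normal((30, 2))
        nu = 0.3
        model = GradientBoostingTrees(n_estimators=1, max_leaves=1,
                                      reg_lambda=0.0, learning_rate=nu).fit(X, y)
        # from p0 = 0.5: g = 0.5 - y, h = 0.25; w* = -sum g / sum h
        w_expect = -np.sum(0.5 - y) / (0.25 * len(y))
        raw = model.decision_function(X)
        assert np.allclose(raw, nu * w_expect)

    def test_separable_fixture_perfect_auc(self, rng):
        X, y = _blobs(rng)
        model = GradientBoostingTrees(n_estimators=20, max_leaves=7).fit(X, y)
        assert roc_auc_score(y, model.predict_proba(X)[:, 1]) == 1.0

    def test_deterministic_tree_structures(self, rng):
        X, y = _blobs(rng)
        m1 = GradientBoostingTrees(n_estimators=5, max_leaves=5).fit(X, y)
        m2 = GradientBoostingTrees(n_estimators=5, max_leaves=5).fit(X, y)
        for t1, t2 in zip(m1.trees_, m2.trees_):
            assert [(n.feature, n.threshold, n.value) for n in t1.nodes] == \
                   [(n.feature, n.threshold, n.value) for n in t2.nodes]

    def test_leaf_count_bounded(self, rng):
        X, y = _blobs(rng)
        model = GradientBoostingTrees(n_estimators=5, max_leaves=4).fit(X, y)
        assert all(t.n_leaves <= 4 for t in model.trees_)

    def test_empty_model_scores_half(self, rng):
        X, y = _blobs(rng, n=10)
        model = GradientBoostingTrees(n_estimators=0).fit(X, y)
        assert np.allclose(model.predict_proba(X)[:, 1], 0.5)

    def test_manual_stump_routing(self):
        tree = _RegressionTree(max_leaves=2, lam=0.0)
        tree.nodes = [_TreeNode(feature=0, threshold=0.5, left=1, right=2),
                      _TreeNode(value=-1.0), _TreeNode(value=2.0)]
        model = GradientBoostingTrees(n_estimators=1, learning_rate=0.1)
        model.trees_ = [tree]
        model.classes_ = np.array([0, 1])
        p = model.predict_proba(np.array([[0.0], [1.0]]))[:, 1]
        expect = 1 / (1 + np.exp(-np.array([-0.1, 0.2])))
        assert np.allclose(p, expect)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            GradientBoostingTrees().fit(rng.standard_normal((5, 2)), np.zeros(5))

    def test_lightgbm_backend_parity_on_held_out_auc(self, rng):
        """The from-scratch trainer and the established histogram-based
        library agree to within 0.05 held-out AUC at matched settings."""
        lgb = pytest.importorskip("lightgbm")  # noqa: F841
        X = rng.standard_normal((300, 5))
        logit = X[:, 0] * 1.5 - X[:, 1] + 0.5 * X[:, 2] * X[:, 3]
        y = (rng.random(300) < 1 / (1 + np.exp(-logit))).astype(int)
        Xtr, Xte, ytr, yte = X[:200], X[200:], y[:200], y[200:]
        kw = dict(n_estimators=40, max_leaves=15, reg_lambda=1.0,
                  learning_rate=0.1)
        a = GradientBoostingTrees(**kw).fit(Xtr, ytr)
        b = GradientBoostingTrees(backend="lightgbm", **kw).fit(Xtr, ytr)
        auc_a = roc_auc_score(yte, a.predict_proba(Xte)[:, 1])
        auc_b = roc_auc_score(yte, b.predict_proba(Xte)[:, 1])
        assert abs(auc_a - auc_b) < 0.05


# ---------------------------------------------------------------------------
# soft voting
# ---------------------------------------------------------------------------

class TestSoftVote:
    def test_weighted_arithmetic(self):
        score, label = soft_vote([1.0, 0.2, 0.5], [1.0, 0.9, 0.5])
        assert np.allclose(score, [1.0, 0.4 * 0.2 + 0.6 * 0.9, 0.5])
        assert label.tolist() == [1, 1, 0]  # 0.5 is NOT positive (strict >)

    def test_boundary_strictness(self):
        _, label = soft_vote([0.5], [0.5])
        assert label[0] == 0

    def test_convex_combination_bounds(self, rng):
        cd, cg = rng.random(100), rng.random(100)
        score, _ = soft_vote(cd, cg)
        assert (score >= np.minimum(cd, cg) - 1e-12).all()
        assert (score <= np.maximum(cd, cg) + 1e-12).all()

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            soft_vote([0.5], [0.5], alpha=0.5, beta=0.6)
        with pytest.raises(ValueError):
            soft_vote([0.5], [0.5], alpha=-0.2, beta=1.2)
        with pytest.raises(ValueError):
            soft_vote([0.5], [0.5], threshold=1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            soft_vote([0.5, 0.6], [0.5])

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            soft_vote([1.5], [0.5])

    def test_ensemble_estimator_end_to_end(self, rng):
        X, y = _blobs(rng)
        clf = SoftVotingClassifier(
            dnn=DNNClassifier(hidden_layer_sizes=(8,), epochs=100, seed=0),
            gbm=GradientBoostingTrees(n_estimators=10, max_leaves=5)).fit(X, y)
        cd, cg = clf.member_scores(X)
        p = clf.predict_proba(X)[:, 1]
        assert np.allclose(p, 0.4 * cd + 0.6 * cg)
        assert (clf.predict(X) == (p > 0.5).astype(int)).all()
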