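"""Second-order boosted trees: gradients, split objective, exact-greedy fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ptsarank.boosting import (
    BoostingConfig,
    build_tree,
    fit,
    gbdt_init_score,
    gbdt_leaf_value,
    leaf_weight,
    logistic_gradients,
    model_from_json,
    model_to_json,
    predict_proba,
    BoostedModel,
    split_gain,
    structure_score,
)


class TestLogisticGradients:
    @pytest.mark.parametrize(
        "margin, y, g, h",
        [(0.0, 1, -0.5, 0.25), (0.0, 0, 0.5, 0.25)],
    )
    def test_values_at_zero_margin(self, margin, y, g, h):
        got_g, got_h = logistic_gradients(margin, y)
        assert got_g == pytest.approx(g) and got_h == pytest.approx(h)

    @pytest.mark.parametrize("margin", [-1.0, 1.0])
    @pytest.mark.parametrize("y", [0, 1])
    def test_gradient_matches_finite_difference(self, margin, y):
        def loss(f):
            p = 1 / (1 + np.exp(-f))
            return -(y * np.log(p) + (1 - y) * np.log(1 - p))

        eps = 1e-6
        numeric_g = (loss(margin + eps) - loss(margin - eps)) / (2 * eps)
        eps_h = 1e-4  # larger step: second differences cancel catastrophically
        numeric_h = (loss(margin + eps_h) - 2 * loss(margin) + loss(margin - eps_h)) / eps_h**2
        g, h = logistic_gradients(margin, y)
        assert g == pytest.approx(numeric_g, abs=1e-6)
        assert h == pytest.approx(numeric_h, abs=1e-4)


class TestLeafAndStructure:
    def test_leaf_weight_arithmetic(self):
        assert leaf_weight(2.0, 3.0, 1.0) == pytest.approx(-0.5)
        assert leaf_weight(0.0, 5.0, 2.0) == 0.0

    def test_leaf_weight_shrinks_to_zero(self):
        prev = abs(leaf_weight(3.0, 1.0, 0.0))
        for lam in (1.0, 10.0, 1e3, 1e9):
            cur = abs(leaf_weight(3.0, 1.0, lam))
            assert cur < prev
            prev = cur
        assert prev < 1e-8

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(ValueError):
            leaf_weight(1.0, -2.0, 1.0)

    def test_structure_score_single_pure_leaf(self):
        assert structure_score([(0.0, 1.0)], lam=1.0, gamma=0.7) == pytest.approx(0.7)

    def test_structure_score_two_leaves(self):
        assert structure_score([(1.0, 1.0), (-1.0, 1.0)], lam=1.0, gamma=0.0) == pytest.approx(-0.5)

    def test_structure_score_matches_termwise_sum(self, rng):
        stats = [(rng.normal(), rng.random() + 0.1) for _ in range(8)]
        lam, gamma = 0.3, 0.2
        expected = -0.5 * sum(G * G / (H + lam) for G, H in stats) + gamma * len(stats)
        assert structure_score(stats, lam, gamma) == pytest.approx(expected, abs=1e-12)


class TestSplitGain:
    def test_hand_value(self):
        assert split_gain(1.0, 1.0, -1.0, 1.0, 0.0, 0.0) == pytest.approx(1.0)

    def test_gamma_can_reject_split(self):
        assert split_gain(1.0, 1.0, -1.0, 1.0, 0.0, 1.5) < 0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.floats(-10, 10), st.floats(0.01, 10),
        st.floats(-10, 10), st.floats(0.01, 10),
    )
    def test_nonnegative_without_regularization(self, GL, HL, GR, HR):
        # Cauchy-Schwarz: splitting never hurts when lambda = gamma = 0
        assert split_gain(GL, HL, GR, HR, 0.0, 0.0) >= -1e-9


def brute_force_best_gain(X, g, h, lam, gamma, min_child_hessian):
    """Independent exhaustive enumeration of every (feature, threshold) gain."""
    best = None
    n, d = X.shape
    for j in range(d):
        for thr in np.unique(X[:, j]):
            left = X[:, j] <= thr
            if left.all() or not left.any():
                continue
            HL, HR = h[left].sum(), h[~left].sum()
            if HL < min_child_hessian or HR < min_child_hessian:
                continue
            GL, GR = g[left].sum(), g[~left].sum()
            gain = split_gain(GL, HL, GR, HR, lam, gamma)
            if best is None or gain > best:
                best = gain
    return best


class TestBuildTree:
    def test_identical_labels_give_single_newton_leaf(self):
        X = np.arange(6.0).reshape(-1, 1)
        g, h = logistic_gradients(np.zeros(6), np.ones(6))
        tree = build_tree(X, g, h, BoostingConfig(lam=1.0))
        assert tree.is_leaf
        assert tree.weight == pytest.approx(-g.sum() / (h.sum() + 1.0))

    def test_one_dimensional_toy_threshold(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([0, 0, 1, 1])
        g, h = logistic_gradients(np.zeros(4), y)
        tree = build_tree(X, g, h, BoostingConfig(max_depth=1, lam=0.0, min_child_hessian=0.0))
        assert not tree.is_leaf
        assert 2.0 < tree.split_threshold < 3.0

    def test_every_internal_node_is_brute_force_optimal(self, rng):
        for _ in range(5):
            X = rng.normal(size=(30, 5))
            y = rng.integers(0, 2, size=30)
            g, h = logistic_gradients(rng.normal(size=30), y)
            cfg = BoostingConfig(max_depth=3, lam=1.0, gamma=0.1, min_child_hessian=1e-3)
            tree = build_tree(X, g, h, cfg)
            # walk the tree re-deriving the sample subsets
            stack = [(tree, np.ones(30, dtype=bool))]
            while stack:
                node, mask = stack.pop()
                if node.is_leaf:
                    continue
                left = X[:, node.split_feature] <= node.split_threshold
                chosen_gain = split_gain(
                    g[mask & left].sum(), h[mask & left].sum(),
                    g[mask & ~left].sum(), h[mask & ~left].sum(),
                    cfg.lam, cfg.gamma,
                )
                best = brute_force_best_gain(
                    X[mask], g[mask], h[mask], cfg.lam, cfg.gamma, cfg.min_child_hessian
                )
                assert chosen_gain == pytest.approx(best, abs=1e-10)
                stack.append((node.left, mask & left))
                stack.append((node.right, mask & ~left))

    def test_accepted_split_changes_structure_score_by_gain(self, rng):
        X = rng.normal(size=(40, 4))
        y = rng.integers(0, 2, size=40)
        g, h = logistic_gradients(np.zeros(40), y)
        lam = 1.0
        tree = build_tree(X, g, h, BoostingConfig(max_depth=2, lam=lam, gamma=0.0))
        for node in tree.internal_nodes():
            G, H = node.node_stats
            (GL, HL), (GR, HR) = node.left.node_stats, node.right.node_stats
            parent_term = structure_score([(G, H)], lam, 0.0)
            child_term = structure_score([(GL, HL), (GR, HR)], lam, 0.0)
            bracketed = split_gain(GL, HL, GR, HR, lam, 0.0)
            assert parent_term - child_term == pytest.approx(bracketed, abs=1e-10)


class TestFit:
    def test_separable_toy_reaches_perfect_accuracy(self, rng):
        X = np.vstack([rng.normal(-2, 0.3, size=(15, 2)), rng.normal(2, 0.3, size=(15, 2))])
        y = np.array([0] * 15 + [1] * 15)
        model = fit(X, y, BoostingConfig(n_rounds=20))
        assert np.array_equal(predict_proba(model, X) > 0.5, y.astype(bool))

    def test_training_loss_non_increasing(self, rng):
        X = rng.normal(size=(50, 3))
        y = (X[:, 0] + rng.normal(0, 0.5, size=50) > 0).astype(int)
        cfg = BoostingConfig(n_rounds=30, learning_rate=0.1)
        model = fit(X, y, cfg)
        margin = np.zeros(50)
        losses = []
        for tree in model.trees:
            margin += cfg.learning_rate * tree.predict(X)
            p = 1 / (1 + np.exp(-margin))
            losses.append(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_first_round_leaves_are_newton_steps_at_zero_margin(self, rng):
        X = rng.normal(size=(20, 2))
        y = rng.integers(0, 2, size=20)
        while len(set(y)) < 2:
            y = rng.integers(0, 2, size=20)
        cfg = BoostingConfig(n_rounds=1)
        model = fit(X, y, cfg)
        g, h = logistic_gradients(np.zeros(20), y)
        expected = build_tree(X, g, h, cfg)
        assert np.allclose(model.trees[0].predict(X), expected.predict(X))

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit(rng.normal(size=(10, 2)), np.ones(10, dtype=int), BoostingConfig())

    def test_zero_tree_model_predicts_half(self, rng):
        model = BoostedModel(base_score=0.0, trees=[], config=BoostingConfig())
        assert np.all(predict_proba(model, rng.normal(size=(5, 2))) == 0.5)

    def test_prediction_matches_margin_accumulation_oracle(self, rng):
        X = rng.normal(size=(25, 3))
        y = rng.integers(0, 2, size=25)
        while len(set(y)) < 2:
            y = rng.integers(0, 2, size=25)
        cfg = BoostingConfig(n_rounds=7, learning_rate=0.3)
        model = fit(X, y, cfg)
        margin = np.zeros(25)
        for tree in model.trees:
            margin += cfg.learning_rate * tree.predict(X)
        assert np.allclose(predict_proba(model, X), 1 / (1 + np.exp(-margin)), atol=1e-12)

    def test_sparse_and_dense_views_predict_identically(self, rng):
        X = (rng.random((30, 6)) < 0.2).astype(float)
        y = rng.integers(0, 2, size=30)
        while len(set(y)) < 2:
            y = rng.integers(0, 2, size=30)
        model = fit(X, y, BoostingConfig(n_rounds=5))
        from scipy import sparse

        X_sparse = sparse.csr_matrix(X).toarray()  # reconstructed dense view
        assert np.array_equal(predict_proba(model, X), predict_proba(model, X_sparse))

    def test_matches_reference_xgboost_library(self, rng):
        xgb = pytest.importorskip("xgboost")
        X = rng.normal(size=(40, 5))
        y = (X[:, 0] + 0.5 * rng.normal(size=40) > 0).astype(int)
        cfg = BoostingConfig(n_rounds=10, max_depth=3, learning_rate=0.1,
                             lam=1.0, gamma=0.0, min_child_hessian=0.0)
        ours = predict_proba(fit(X, y, cfg), X)
        clf = xgb.XGBClassifier(
            n_estimators=10, max_depth=3, learning_rate=0.1, reg_lambda=1.0,
            gamma=0.0, min_child_weight=0.0, tree_method="exact",
            base_score=0.5, objective="binary:logistic",
        )
        clf.fit(X, y)
        theirs = clf.predict_proba(X)[:, 1]
        # reference library computes in float32
        assert np.abs(ours - theirs).max() < 1e-5


class TestShrinkage:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(-5, 5), st.floats(0.01, 5), st.floats(0, 10), st.floats(0, 10))
    def test_lambda_never_increases_leaf_magnitude(self, G, H, lam1, extra):
        lam2 = lam1 + extra
        assert abs(leaf_weight(G, H, lam2)) <= abs(leaf_weight(G, H, lam1)) + 1e-12


class TestClassicalGbdtOps:
    def test_balanced_labels_start_at_zero(self):
        assert gbdt_init_score([1, -1, 1, -1]) == 0.0

    def test_half_log_three(self):
        # ybar = 0.5 -> 0.5 * log(3)
        assert gbdt_init_score([1, 1, 1, -1]) == pytest.approx(0.5 * np.log(3))

    def test_antisymmetry(self):
        assert gbdt_init_score([1, 1, -1]) == pytest.approx(-gbdt_init_score([-1, -1, 1]))

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            gbdt_init_score([1, 1, 1])

    def test_leaf_value_single_residual(self):
        assert gbdt_leaf_value([0.5]) == pytest.approx(0.5 / (0.5 * 1.5))

    def test_leaf_value_zero_residuals_rejected(self):
        with pytest.raises(ValueError):
            gbdt_leaf_value([0.0, 0.0])

    def test_leaf_value_sign_follows_residual_sum(self, rng):
        for _ in range(10):
            r = rng.uniform(-1.5, 1.5, size=6)
            if abs(r).sum() == 0 or r.sum() == 0:
                continue
            assert np.sign(gbdt_leaf_value(r)) == np.sign(r.sum())


def test_model_json_round_trip(rng):
    X = rng.normal(size=(20, 3))
    y = rng.integers(0, 2, size=20)
    while len(set(y)) < 2:
        y = rng.integers(0, 2, size=20)
    model = fit(X, y, BoostingConfig(n_rounds=4))
    restored = model_from_json(model_to_json(model))
    assert np.array_equal(predict_proba(model, X), predict_proba(restored, X))
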