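"""Network primitives against loop oracles, gradient checks, training."""

import numpy as np
import pytest

import heterodualnet as hdn
from heterodualnet.dualcnn import (_branch_backward, _softmax_vjp,
                                   branch_forward, init_branch, max_pool)

from .conftest import (branch_forward_oracle, conv_relu_oracle,
                       max_pool_oracle)


class _ConstantContext:
    """Embedding builder whose output depends only on the pair's label
    membership: positives map to one fixed matrix, negatives to another
    (a linearly separable toy)."""

    def __init__(self, width, positive_drugs, seed=0):
        rng = np.random.default_rng(seed)
        self.width = width
        self.C1 = rng.uniform(0, 1, (5, width))
        self.C2 = rng.uniform(0, 1, (5, width))
        self.positive_drugs = set(positive_drugs)

    def build_batch(self, drugs, diseases, variant):
        out = np.empty((len(drugs), 5, self.width))
        for b, i in enumerate(drugs):
            out[b] = self.C1 if i in self.positive_drugs else self.C2
        return out


def _tiny_config(**kw):
    return hdn.ModelConfig(**{"epochs": 5, "batch_size": 8,
                              "dropout_rate": 0.0, **kw})


class TestConvPool:
    def test_zero_filter_zero_bias(self):
        X = np.random.default_rng(0).random((1, 1, 5, 8))
        W = np.zeros((2, 1, 3, 5))
        out = hdn.conv_relu(X, W, np.zeros(2))
        assert np.all(out == 0)

    def test_bias_clamping(self):
        X = np.random.default_rng(0).random((1, 1, 5, 8))
        W = np.zeros((1, 1, 3, 5))
        assert np.all(hdn.conv_relu(X, W, np.array([-1.0])) == 0)
        np.testing.assert_allclose(
            hdn.conv_relu(X, W, np.array([0.7])), 0.7)

    @pytest.mark.parametrize("seed", range(3))
    def test_conv_matches_sliding_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((1, 5, 8))
        W = rng.standard_normal((1, 1, 3, 5))
        b = rng.standard_normal(1)
        out = hdn.conv_relu(X[None], W, b)[0]
        np.testing.assert_allclose(out, conv_relu_oracle(X, W, b),
                                   atol=1e-12)

    def test_pool_constant_map(self):
        S = np.full((1, 2, 5, 8), 3.0)
        out = max_pool(S, (1, 2))
        assert out.shape == (1, 2, 5, 4)
        assert np.all(out == 3.0)

    def test_pool_row_example(self):
        S = np.array([1.0, 2.0, 5.0, 4.0]).reshape(1, 1, 1, 4)
        np.testing.assert_array_equal(max_pool(S, (1, 2)).ravel(), [2, 5])

    @pytest.mark.parametrize("width", [8, 9])  # even and odd widths
    def test_pool_matches_block_max_oracle(self, width):
        rng = np.random.default_rng(width)
        S = rng.random((2, 3, 5, width))
        out = max_pool(S, (1, 2))
        for b in range(2):
            np.testing.assert_allclose(out[b],
                                       max_pool_oracle(S[b], (1, 2)))


class TestBranchForward:
    @pytest.fixture()
    def state_and_config(self):
        cfg = _tiny_config()
        rng = np.random.default_rng(3)
        return init_branch(cfg, 12, rng), cfg

    def test_scores_sum_to_one(self, state_and_config):
        state, cfg = state_and_config
        X = np.random.default_rng(0).random((4, 5, 12))
        _, h = branch_forward(X, state, cfg)
        np.testing.assert_allclose(h.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(h > 0)

    def test_zero_dense_head_gives_half_half(self, state_and_config):
        state, cfg = state_and_config
        state.Wd[:] = 0.0
        state.bd[:] = 0.0
        X = np.random.default_rng(0).random((5, 12))
        _, h = branch_forward(X, state, cfg)
        np.testing.assert_allclose(h, [0.5, 0.5])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_straight_line_oracle(self, seed):
        cfg = _tiny_config()
        rng = np.random.default_rng(seed)
        state = init_branch(cfg, 12, rng)
        X = rng.random((5, 12))
        _, h = branch_forward(X, state, cfg)
        np.testing.assert_allclose(h, branch_forward_oracle(X, state, cfg),
                                   atol=1e-10)

    def test_shape_mismatch_raises(self, state_and_config):
        state, cfg = state_and_config
        X = np.random.default_rng(0).random((2, 5, 20))  # wrong width
        with pytest.raises(hdn.ConfigurationError):
            branch_forward(X, state, cfg)


class TestFusionAndLoss:
    def test_fusion_boundaries(self):
        hL, hR = np.array([0.8, 0.2]), np.array([0.4, 0.6])
        np.testing.assert_allclose(hdn.fuse_scores(hL, hR, 1.0), hL)
        np.testing.assert_allclose(hdn.fuse_scores(hL, hR, 0.0), hR)
        np.testing.assert_allclose(hdn.fuse_scores(hL, hR, 0.5), [0.6, 0.4])

    def test_fusion_stays_normalized(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            hL = hdn.softmax(rng.standard_normal(2))
            hR = hdn.softmax(rng.standard_normal(2))
            a = rng.random()
            assert hdn.fuse_scores(hL, hR, a).sum() == pytest.approx(1.0)

    def test_fusion_rejects_bad_alpha(self):
        with pytest.raises(hdn.ConfigurationError):
            hdn.fuse_scores(np.array([0.5, 0.5]), np.array([0.5, 0.5]), 1.5)

    def test_loss_zero_at_target(self):
        y = np.array([1.0, 0.0])
        assert hdn.pair_loss(y, y, y, 0.5) == 0.0

    def test_loss_half_half_example(self):
        assert hdn.pair_loss([0.5, 0.5], [0.9, 0.1], [0.0, 1.0], 1.0) \
            == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(3))
    def test_loss_matches_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        hL, hR = rng.random(2), rng.random(2)
        y = np.array([1.0, 0.0])
        a = rng.random()
        expected = a * ((hL[0] - 1) ** 2 + hL[1] ** 2) \
            + (1 - a) * ((hR[0] - 1) ** 2 + hR[1] ** 2)
        assert hdn.pair_loss(hL, hR, y, a) == pytest.approx(expected,
                                                            abs=1e-12)


def _analytic_grads(X, state, cfg, y, weight):
    """dL/dparams for one branch of loss = weight * ||h - y||^2."""
    cache = {}
    branch_forward(X, state, cfg, cache=cache)
    h = cache["h"]
    g = weight * 2.0 * (h - y)
    dz = _softmax_vjp(h, g)
    return _branch_backward(dz, state, cfg, cache), h


class TestGradients:
    @pytest.mark.parametrize("param", ["W1", "b1", "W2", "b2", "Wd", "bd"])
    def test_finite_difference_agreement(self, param):
        """Analytic backprop of the squared-error loss vs central finite
        differences, to 1e-4 relative error on sampled entries."""
        cfg = _tiny_config()
        rng = np.random.default_rng(11)
        state = init_branch(cfg, 12, rng)
        X = rng.random((3, 5, 12))
        y = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        grads, _ = _analytic_grads(X, state, cfg, y, weight=0.7)
        arr = state.params()[param]
        flat = arr.ravel()
        eps = 1e-6
        for idx in rng.choice(flat.size, size=min(6, flat.size),
                              replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            _, h_plus = _analytic_grads(X, state, cfg, y, 0.7)
            lp = 0.7 * np.sum((h_plus - y) ** 2)
            flat[idx] = orig - eps
            _, h_minus = _analytic_grads(X, state, cfg, y, 0.7)
            lm = 0.7 * np.sum((h_minus - y) ** 2)
            flat[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            analytic = grads[param].ravel()[idx]
            denom = max(abs(numeric), abs(analytic), 1e-8)
            assert abs(numeric - analytic) / denom < 1e-4


class TestTraining:
    def test_separable_toy_converges(self):
        """Positives and negatives with constant distinct embeddings are
        linearly separable, so the loss must fall below 0.05."""
        ctx = _ConstantContext(width=12, positive_drugs=range(10))
        drugs = np.arange(20)
        labels = (drugs < 10).astype(int)
        cfg = _tiny_config(epochs=200, learning_rate=3e-3, seed=0,
                           plateau_tol=0.0)
        model = hdn.train(hdn.TrainingSet(ctx, drugs, np.zeros(20, int),
                                          labels), cfg)
        assert min(model.loss_history) < 0.05
        scores = model.score_batch(ctx, drugs, np.zeros(20, int))
        assert scores[labels == 1].min() > scores[labels == 0].max()

    def test_same_seed_reproduces_losses(self):
        ctx = _ConstantContext(width=12, positive_drugs=range(5))
        drugs = np.arange(10)
        labels = (drugs < 5).astype(int)
        cfg = _tiny_config(epochs=4, dropout_rate=0.3, seed=7)
        runs = [hdn.train(hdn.TrainingSet(ctx, drugs, np.zeros(10, int),
                                          labels), cfg) for _ in range(2)]
        assert runs[0].loss_history == runs[1].loss_history
        np.testing.assert_array_equal(runs[0].left.W1, runs[1].left.W1)

    def test_alpha_one_freezes_right_branch_effect(self):
        ctx = _ConstantContext(width=12, positive_drugs=range(5))
        drugs = np.arange(10)
        labels = (drugs < 5).astype(int)
        cfg = _tiny_config(epochs=3, alpha=1.0, seed=1)
        model = hdn.train(hdn.TrainingSet(ctx, drugs, np.zeros(10, int),
                                          labels), cfg)
        # right branch never updated: fused score equals the left branch's
        X = ctx.build_batch(drugs[:4], np.zeros(4, int), "original")
        _, hL = branch_forward(X, model.left, cfg)
        scores = model.score_batch(ctx, drugs[:4], np.zeros(4, int))
        np.testing.assert_allclose(scores, hL[:, 0], atol=1e-12)
        # and its weights still equal a fresh initialization with the seed
        rng = np.random.default_rng(cfg.seed)
        init_branch(cfg, 12, rng)  # left branch draw
        fresh_right = init_branch(cfg, 12, rng)
        np.testing.assert_array_equal(model.right.W1, fresh_right.W1)

    def test_single_class_rejected(self):
        ctx = _ConstantContext(width=12, positive_drugs=range(5))
        with pytest.raises(ValueError, match="both"):
            hdn.train(hdn.TrainingSet(ctx, np.arange(5), np.zeros(5, int),
                                      np.ones(5, int)), _tiny_config())

    def test_untrained_model_refuses_to_predict(self):
        ctx = _ConstantContext(width=12, positive_drugs=range(5))
        model = hdn.HeteroDualNet(_tiny_config(), 12)
        with pytest.raises(RuntimeError):
            model.predict(ctx, 0, 0)

    def test_inference_is_deterministic(self):
        ctx = _ConstantContext(width=12, positive_drugs=range(5))
        drugs = np.arange(10)
        labels = (drugs < 5).astype(int)
        cfg = _tiny_config(epochs=2, dropout_rate=0.5, seed=3)
        model = hdn.train(hdn.TrainingSet(ctx, drugs, np.zeros(10, int),
                                          labels), cfg)
        s1 = model.score_batch(ctx, drugs, np.zeros(10, int))
        s2 = model.score_batch(ctx, drugs, np.zeros(10, int))
        np.testing.assert_array_equal(s1, s2)
        assert np.all((s1 >= 0) & (s1 <= 1))


class TestCheckpoint:
    def test_round_trip_and_shape_rejection(self, tmp_path):
        ctx = _ConstantContext(width=12, positive_drugs=range(5))
        drugs = np.arange(10)
        labels = (drugs < 5).astype(int)
        cfg = _tiny_config(epochs=2, seed=2)
        model = hdn.train(hdn.TrainingSet(ctx, drugs, np.zeros(10, int),
                                          labels), cfg)
        path = tmp_path / "model.npz"
        model.save(path)
        back = hdn.HeteroDualNet.load(path, expected_width=12)
        s1 = model.score_batch(ctx, drugs, np.zeros(10, int))
        s2 = back.score_batch(ctx, drugs, np.zeros(10, int))
        np.testing.assert_array_equal(s1, s2)
        with pytest.raises(hdn.ConfigurationError, match="width"):
            hdn.HeteroDualNet.load(path, expected_width=40)

    def test_odd_conv_shape_required(self):
        with pytest.raises(hdn.ConfigurationError, match="odd"):
            hdn.ModelConfig(conv1_shape=(2, 5))
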