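import math

import numpy as np
import pytest

from eegproto.nn import (
    ABLATION_VARIANTS,
    ResNetSE,
    ResNetSESpec,
    ResTcnSEAttention,
    ResTcnSpec,
    TrainConfig,
    bce_loss,
    focal_loss,
    mixup_batch,
    train_model,
)
from eegproto.nn.autodiff import Tensor
from eegproto.nn.layers import AttentionPool, SEBlock
from eegproto.records import ConfigurationError


class TestResNetSE:
    def test_output_scalar_probability(self, rng):
        m = ResNetSE(384, 5, spec=ResNetSESpec.tiny(), seed=0)
        p = m.forward((rng.standard_normal((3, 384, 5)),))
        assert p.data.shape == (3, 1)
        assert np.all((p.data > 0) & (p.data < 1))

    def test_internal_time_lengths(self):
        m = ResNetSE(384, 5, spec=ResNetSESpec.tiny(), seed=0)
        assert m.time_lengths(384) == [384, 192, 96, 48]

    def test_parameter_count_full_scale(self):
        m = ResNetSE(384, 5, seed=0)
        assert abs(m.n_params() - 928_000) / 928_000 <= 0.15

    def test_invalid_window_length(self):
        with pytest.raises(ConfigurationError):
            ResNetSE(250, 5, seed=0)


class TestResTcn:
    def test_output_scalar(self, rng):
        m = ResTcnSEAttention(256, 5, spec=ResTcnSpec.tiny(), seed=0)
        p = m.forward((rng.standard_normal((2, 256, 5)),
                       rng.standard_normal((2, 175)),
                       rng.standard_normal((2, 167))))
        assert p.data.shape == (2, 1)
        assert np.all((p.data > 0) & (p.data < 1))

    def test_raw_branch_time_lengths(self):
        m = ResTcnSEAttention(256, 5, spec=ResTcnSpec.tiny(), seed=0)
        assert m.time_lengths(256) == [256, 128, 64, 32, 16, 16]

    def test_zeroed_attention_equals_gap(self, rng):
        m = ResTcnSEAttention(256, 5, spec=ResTcnSpec.tiny(), seed=1)
        for p in m.pool.params():
            p.data[...] = 0.0
        x = (rng.standard_normal((2, 256, 5)), rng.standard_normal((2, 175)),
             rng.standard_normal((2, 167)))
        gap_variant = ResTcnSEAttention(256, 5, spec=ResTcnSpec.tiny(),
                                        use_attention=False, seed=1)
        pool_param_ids = {id(q) for q in m.pool.params()}
        gap_variant.set_weights(
            [w for p, w in zip(m.params(), m.get_weights())
             if id(p) not in pool_param_ids]
        )
        np.testing.assert_allclose(m.forward(x).data, gap_variant.forward(x).data, atol=1e-12)

    def test_ablation_variants_structural(self):
        full = ResTcnSEAttention(256, 5, spec=ResTcnSpec.tiny(), seed=0)
        bare = ResTcnSEAttention(256, 5, spec=ResTcnSpec.tiny(),
                                 use_se=False, use_attention=False, seed=0)
        assert bare.n_params() < full.n_params()
        assert set(ABLATION_VARIANTS) == {
            "res_tcn_se_attention", "res_tcn_se", "res_tcn_attention", "res_tcn",
        }


class TestAttentionPool:
    def test_single_frame_identity(self, rng):
        pool = AttentionPool(4, np.random.default_rng(0))
        x = Tensor(rng.standard_normal((2, 1, 4)))
        np.testing.assert_allclose(pool(x).data, x.data[:, 0, :], atol=1e-12)

    def test_uniform_scores_give_mean(self, rng):
        pool = AttentionPool(4, np.random.default_rng(0))
        for p in pool.params():
            p.data[...] = 0.0
        x = Tensor(rng.standard_normal((3, 7, 4)))
        np.testing.assert_allclose(pool(x).data, x.data.mean(axis=1), atol=1e-12)

    def test_weights_nonneg_sum_one(self, rng):
        pool = AttentionPool(6, np.random.default_rng(2))
        w = pool.weights(Tensor(rng.standard_normal((4, 9, 6)))).data
        assert np.all(w >= 0)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)

    def test_dominant_score_selects_frame(self, rng):
        pool = AttentionPool(3, np.random.default_rng(0))
        x = rng.standard_normal((1, 5, 3))
        # drive the score head so frame 2 dominates
        pool.score1.w.data[...] = 0.0
        pool.score1.b.data[...] = 0.0
        pool.score2.w.data[...] = 0.0
        scores = np.zeros((1, 5, 1))
        scores[0, 2, 0] = 60.0

        class FakeHead:
            def __call__(self, t, training=False, rng=None):
                return Tensor(scores)

        pool.score2 = FakeHead()
        out = pool(Tensor(x))
        np.testing.assert_allclose(out.data, x[:, 2, :], atol=1e-10)


class TestSEBlock:
    def test_gate_in_unit_interval(self, rng):
        se = SEBlock(16, np.random.default_rng(0))
        g = se.gate(Tensor(rng.standard_normal((4, 10, 16)))).data
        assert np.all((g > 0) & (g < 1))

    def test_bottleneck_rule(self):
        se = SEBlock(64, np.random.default_rng(0))
        assert se.fc1.w.shape == (64, 8)
        se2 = SEBlock(256, np.random.default_rng(0))
        assert se2.fc1.w.shape == (256, 32)


class TestFocalLoss:
    def test_confident_correct_is_zero(self):
        loss = focal_loss(np.array([1.0]), Tensor(np.array([[1.0 - 1e-9]])))
        assert float(loss.data) == pytest.approx(0.0, abs=1e-6)

    def test_closed_form(self):
        loss = focal_loss(np.array([1.0]), Tensor(np.array([[0.5]])), alpha=0.25, gamma=2.0)
        assert float(loss.data) == pytest.approx(0.25 * 0.25 * math.log(2), rel=1e-9)

    def test_gamma_zero_reduces_to_half_bce(self, rng):
        y = rng.integers(0, 2, 16).astype(float)
        p = Tensor(rng.uniform(0.05, 0.95, (16, 1)))
        f = focal_loss(y, p, alpha=0.5, gamma=0.0)
        b = bce_loss(y, p)
        assert float(f.data) == pytest.approx(0.5 * float(b.data), rel=1e-9)

    def test_finite_at_extremes(self):
        loss = focal_loss(np.array([1.0, 0.0]), Tensor(np.array([[0.0], [1.0]])))
        assert np.isfinite(float(loss.data))


class TestMixup:
    def test_lambda_one_returns_originals(self, rng):
        X = rng.standard_normal((8, 4))
        y = rng.integers(0, 2, 8).astype(float)

        class DegenerateRng:
            def beta(self, a, b):
                return 1.0

            def permutation(self, n):
                return np.arange(n)[::-1]

        (Xm,), ym = mixup_batch((X,), y, 0.2, DegenerateRng())
        np.testing.assert_allclose(Xm, X)
        np.testing.assert_allclose(ym, y)

    def test_labels_in_unit_interval(self, rng):
        y = rng.integers(0, 2, 32).astype(float)
        X = rng.standard_normal((32, 4))
        for seed in range(5):
            _, ym = mixup_batch((X,), y, 0.2, np.random.default_rng(seed))
            assert np.all((ym >= 0) & (ym <= 1))

    def test_column_means_invariant(self, rng):
        X = rng.standard_normal((32, 6))
        y = rng.integers(0, 2, 32).astype(float)
        (Xm,), _ = mixup_batch((X,), y, 0.4, np.random.default_rng(3))
        np.testing.assert_allclose(Xm.mean(axis=0), X.mean(axis=0), atol=1e-12)

    def test_batch_of_one_raises(self, rng):
        with pytest.raises(ConfigurationError):
            mixup_batch((np.zeros((1, 3)),), np.zeros(1), 0.2, rng)


def _separable_batch(n=120, w=32, seed=0):
    """Trivially separable windows: class 1 has a strong channel offset
    pattern that survives convolutional processing."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    X = rng.standard_normal((n, w, 2)) * 0.1
    t = np.arange(w)
    X[y == 1, :, 0] += np.sin(2 * np.pi * 4 * t / w)
    X[y == 0, :, 0] += np.sin(2 * np.pi * 1 * t / w)
    return X, y.astype(np.int64)


class TestTrainModel:
    def test_learns_separable_data(self):
        X, y = _separable_batch()
        m = ResNetSE(32, 2, spec=ResNetSESpec.tiny(), seed=0)
        cfg = TrainConfig(epochs=10, batch_size=32, loss="bce", mixup_alpha=0.0,
                          schedule=None, seed=0)
        history = train_model(m, (X,), y, (X[:40],), y[:40], cfg)
        assert max(history["acc"]) >= 0.95

    def test_best_weights_restored(self):
        X, y = _separable_batch(n=60)
        m = ResNetSE(32, 2, spec=ResNetSESpec.tiny(), seed=1)
        cfg = TrainConfig(epochs=4, batch_size=32, loss="bce", mixup_alpha=0.0,
                          schedule=None, seed=1)
        history = train_model(m, (X,), y, (X[:30],), y[:30], cfg)
        assert history["best_val_auc"] == max(history["val_auc"])

    def test_deterministic_across_runs(self):
        X, y = _separable_batch(n=60)
        histories = []
        for _ in range(2):
            m = ResNetSE(32, 2, spec=ResNetSESpec.tiny(), seed=5)
            cfg = TrainConfig(epochs=3, batch_size=32, loss="focal", mixup_alpha=0.2,
                              schedule=None, seed=5)
            histories.append(train_model(m, (X,), y, (X[:20],), y[:20], cfg))
        assert histories[0]["loss"] == histories[1]["loss"]
        assert histories[0]["val_auc"] == histories[1]["val_auc"]

    def test_empty_training_set_raises(self):
        m = ResNetSE(32, 2, spec=ResNetSESpec.tiny(), seed=0)
        with pytest.raises(ConfigurationError):
            train_model(m, (np.empty((0, 32, 2)),), np.empty(0),
                        (np.empty((0, 32, 2)),), np.empty(0), TrainConfig(epochs=1))


class TestSchedules:
    def test_cosine_restarts_shape(self):
        from eegproto.nn.training import _cosine_restarts_lr

        lrs = [_cosine_restarts_lr(e, 1e-3, 10, 2, 1e-5) for e in range(30)]
        assert lrs[0] == pytest.approx(1e-3)
        assert lrs[10] == pytest.approx(1e-3)  # restart
        assert lrs[9] < lrs[10]
        assert min(lrs) >= 1e-5
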