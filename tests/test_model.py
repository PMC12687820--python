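import dataclasses

import numpy as np
import pytest

from topobow import model as M
from topobow.model import TopoBowNet, TopoBowNetConfig, cosine_lr, train


def _separable(rng, n=100, dim=950):
    w = rng.normal(size=dim)
    X = rng.normal(size=(n, dim)).astype(np.float32)
    y = (X @ w > 0).astype(int)
    return X, y


class TestConfig:
    def test_default_segmentation_5x190_10_heads(self):
        cfg = TopoBowNetConfig()
        assert cfg.n_segments * cfg.segment_len == 950
        assert cfg.segment_len == 190
        assert cfg.head_dim == 19

    def test_indivisible_segments_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            TopoBowNetConfig(input_dim=951)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError, match="heads"):
            TopoBowNetConfig(input_dim=950, n_segments=5, n_heads=7)


class TestForward:
    def test_attention_rows_sum_to_one(self, rng):
        net = TopoBowNet(TopoBowNetConfig(seed=0))
        X = rng.normal(size=(8, 950))
        logits, attn = net.forward(X)
        assert attn.shape == (8, 5, 5)
        assert np.allclose(attn.sum(axis=-1), 1.0, atol=1e-6)
        assert logits.shape == (8, 2)

    def test_eval_mode_deterministic(self, rng):
        net = TopoBowNet(TopoBowNetConfig(seed=0))
        X = rng.normal(size=(4, 950))
        l1, _ = net.forward(X)
        l2, _ = net.forward(X)
        assert np.array_equal(l1, l2)

    def test_probabilities_sum_to_one(self, rng):
        net = TopoBowNet(TopoBowNetConfig(seed=0))
        p = net.predict_proba(rng.normal(size=(6, 950)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_noise_off_train_equals_eval(self, rng):
        """With noise_sd=0 and all dropouts 0, train-mode forward is
        identical to eval-mode forward."""
        cfg = TopoBowNetConfig(
            seed=0, noise_sd=0.0, attn_dropout=0.0,
            head_layers=((1024, 0.0), (512, 0.0), (256, 0.0), (1024, 0.0)))
        net = TopoBowNet(cfg)
        X = rng.normal(size=(5, 950))
        lt, _ = net.forward(X, train=True)
        le, _ = net.forward(X, train=False)
        assert np.array_equal(lt, le)

    def test_noise_changes_train_forward(self, rng):
        net = TopoBowNet(TopoBowNetConfig(seed=0))
        X = rng.normal(size=(5, 950))
        lt, _ = net.forward(X, train=True)
        le, _ = net.forward(X, train=False)
        assert not np.array_equal(lt, le)

    def test_single_token_attention_is_value_projection(self, rng):
        """With one segment, softmax over one token is identically 1, so
        attention output reduces to the value then output projection."""
        cfg = TopoBowNetConfig(input_dim=40, n_segments=1, n_heads=4,
                               head_layers=((16, 0.0),), seed=0)
        net = TopoBowNet(cfg)
        X = rng.normal(size=(3, 40)).astype(np.float32)
        _, attn, cache = net.forward(X, return_cache=True)
        assert np.allclose(attn, 1.0)
        p = net.params
        expected = (X @ p["Wv"] + p["bv"]) @ p["Wo"] + p["bo"]
        assert np.allclose(cache["F"], expected, atol=1e-5)

    def test_wrong_input_width_rejected(self, rng):
        net = TopoBowNet(TopoBowNetConfig(seed=0))
        with pytest.raises(ValueError, match="width"):
            net.forward(rng.normal(size=(2, 900)))


class TestGradients:
    def test_all_parameter_groups_receive_gradient(self, rng):
        cfg = TopoBowNetConfig(seed=0)
        net = TopoBowNet(cfg)
        X = rng.normal(size=(16, 950)).astype(np.float32)
        y = rng.integers(0, 2, 16)
        logits, _, cache = net.forward(X, train=True, return_cache=True)
        _, dlogits = net.loss_and_dlogits(logits, y)
        grads = net.backward(dlogits, cache)
        assert set(grads) == set(net.params)
        for name, g in grads.items():
            assert np.any(g != 0), f"zero gradient for {name}"

    def test_analytic_gradient_matches_finite_differences(self, rng):
        old = M.DTYPE
        M.DTYPE = np.float64
        try:
            cfg = TopoBowNetConfig(input_dim=20, n_segments=5, n_heads=2,
                                   head_layers=((12, 0.0), (8, 0.0)),
                                   attn_dropout=0.0, noise_sd=0.0, seed=0)
            net = TopoBowNet(cfg)
            X = rng.normal(size=(6, 20))
            y = rng.integers(0, 2, 6)
            logits, _, cache = net.forward(X, return_cache=True)
            _, dlogits = net.loss_and_dlogits(logits, y)
            grads = net.backward(dlogits, cache)
            for name in ("Wq", "Wk", "Wv", "Wo", "W0", "Wout", "bq", "c1"):
                P = net.params[name]
                for _ in range(3):
                    idx = tuple(rng.integers(0, s) for s in P.shape)
                    eps, orig = 1e-6, P[idx]
                    P[idx] = orig + eps
                    up, _ = net.loss_and_dlogits(net.forward(X)[0], y)
                    P[idx] = orig - eps
                    dn, _ = net.loss_and_dlogits(net.forward(X)[0], y)
                    P[idx] = orig
                    num = (up - dn) / (2 * eps)
                    assert abs(num - grads[name][idx]) <= 1e-6 + 1e-4 * abs(num)
        finally:
            M.DTYPE = old


class TestTraining:
    def test_memorizes_separable_points(self, rng):
        X, y = _separable(rng, n=100)
        cfg = TopoBowNetConfig(epochs=100, seed=0)
        trained = train(X, y, config=cfg)
        assert (trained.predict(X) == y).mean() >= 0.95

    def test_separable_set_fit_quickly(self, rng):
        X, y = _separable(rng, n=200, dim=950)
        cfg = TopoBowNetConfig(epochs=100, seed=0)
        trained = train(X, y, config=cfg)
        assert (trained.predict(X) == y).mean() >= 0.99

    def test_loss_trend_decreasing_early(self, rng):
        X, y = _separable(rng, n=120)
        cfg = TopoBowNetConfig(epochs=10, seed=0)
        trained = train(X, y, config=cfg)
        deltas = np.diff(trained.history["loss"])
        assert np.median(deltas) < 0

    def test_best_epoch_snapshot_property(self, rng):
        X, y = _separable(rng, n=80)
        Xv, yv = X[:20], y[:20]
        cfg = TopoBowNetConfig(epochs=15, seed=0)
        trained = train(X[20:], y[20:], Xv, yv, config=cfg)
        accs = trained.history["val_accuracy"]
        assert trained.best_val_accuracy == max(accs)
        assert trained.best_val_accuracy >= accs[0]
        # restored parameters reproduce the snapshot accuracy
        acc_now = (trained.predict(Xv) == yv).mean()
        assert np.isclose(acc_now, trained.best_val_accuracy)

    def test_training_reproducible_given_seed(self, rng):
        X, y = _separable(rng, n=60)
        cfg = TopoBowNetConfig(epochs=5, seed=3)
        t1 = train(X, y, config=cfg)
        t2 = train(X, y, config=cfg)
        assert np.allclose(t1.history["loss"], t2.history["loss"])
        for k in t1.model.params:
            assert np.array_equal(t1.model.params[k], t2.model.params[k])

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 950))
        with pytest.raises(ValueError, match="both classes"):
            train(X, np.zeros(20, dtype=int),
                  config=TopoBowNetConfig(epochs=1))

    def test_cosine_schedule_endpoints(self):
        assert cosine_lr(1e-4, 0, 500) == pytest.approx(1e-4)
        assert cosine_lr(1e-4, 500, 500) == pytest.approx(0.0, abs=1e-12)
        assert cosine_lr(1e-4, 250, 500) == pytest.approx(5e-5)


class TestAttentionMap:
    def test_segment_scores_sum_to_one(self, rng):
        net = TopoBowNet(TopoBowNetConfig(seed=0))
        scores = net.attention_map(rng.normal(size=(5, 950)))
        assert scores.shape == (5, 5)
        assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-6)

    def test_zeroed_query_key_gives_uniform_attention(self, rng):
        net = TopoBowNet(TopoBowNetConfig(seed=0))
        net.params["Wq"][:] = 0
        net.params["bq"][:] = 0
        net.params["Wk"][:] = 0
        net.params["bk"][:] = 0
        scores = net.attention_map(rng.normal(size=(3, 950)))
        assert np.allclose(scores, 0.2, atol=1e-6)
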