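"""Numerical correctness of the CNN core: forward oracles via scipy,
gradients via central finite differences."""

import numpy as np
import pytest
from scipy.signal import correlate

from illusionprobe import nn


def _numeric_grad(f, x, eps=1e-3):
    """Central-difference gradient of scalar f at float64 array x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


def _rel_err(a, b):
    denom = max(np.abs(a).max(), np.abs(b).max(), 1e-12)
    return np.abs(a - b).max() / denom


class TestConv2d:
    def test_forward_matches_scipy_correlate(self):
        rng = np.random.default_rng(0)
        conv = nn.Conv2d(3, 4, 3, stride=1, rng=rng)
        x = rng.normal(size=(2, 7, 9, 3)).astype(np.float32)
        out = conv.forward(x)
        W = conv.params["W"].astype(np.float64)  # (k, k, cin, cout)
        xp = np.pad(x.astype(np.float64), ((0, 0), (1, 1), (1, 1), (0, 0)))
        for n in range(2):
            for co in range(4):
                expect = np.zeros((7, 9))
                for ci in range(3):
                    full = correlate(xp[n, :, :, ci], W[:, :, ci, co], mode="valid")
                    expect += full
                np.testing.assert_allclose(out[n, :, :, co], expect, atol=1e-4)

    def test_strided_forward_matches_subsampled_dense_conv(self):
        rng = np.random.default_rng(1)
        dense = nn.Conv2d(2, 3, 5, stride=1, rng=np.random.default_rng(7))
        strided = nn.Conv2d(2, 3, 5, stride=2, rng=np.random.default_rng(7))
        x = rng.normal(size=(1, 12, 14, 2)).astype(np.float32)
        np.testing.assert_allclose(
            strided.forward(x), dense.forward(x)[:, ::2, ::2, :], atol=1e-5
        )

    @pytest.mark.parametrize("stride", [1, 2])
    def test_input_and_weight_gradients_match_finite_differences(self, stride):
        rng = np.random.default_rng(2)
        conv = nn.Conv2d(2, 3, 3, stride=stride, rng=rng)
        x = rng.normal(size=(2, 6, 6, 2)).astype(np.float64)
        R = rng.normal(size=conv.forward(x.astype(np.float32)).shape)

        def loss():
            return float((conv.forward(x.astype(np.float32)) * R).sum())

        conv.forward(x.astype(np.float32))
        dx = conv.backward(R.astype(np.float32))
        num_dx = _numeric_grad(loss, x, eps=1e-2)
        assert _rel_err(dx, num_dx) < 5e-3

        W = conv.params["W"]
        W64 = W.astype(np.float64)

        def loss_w():
            conv.params["W"] = W64.astype(np.float32)
            return float((conv.forward(x.astype(np.float32)) * R).sum())

        num_dW = _numeric_grad(loss_w, W64, eps=1e-2)
        conv.params["W"] = W64.astype(np.float32)
        conv.forward(x.astype(np.float32))
        conv.backward(R.astype(np.float32))
        assert _rel_err(conv.grads["W"], num_dW) < 5e-3

    def test_channel_mismatch_is_rejected(self):
        conv = nn.Conv2d(3, 4, 3)
        with pytest.raises(ValueError):
            conv.forward(np.zeros((1, 5, 5, 2), np.float32))


class TestPoolAndPieces:
    def test_maxpool_forward_matches_blockwise_oracle(self):
        rng = np.random.default_rng(3)
        pool = nn.MaxPool2d(2)
        x = rng.normal(size=(2, 6, 8, 3)).astype(np.float32)
        out = pool.forward(x)
        for n in range(2):
            for i in range(3):
                for j in range(4):
                    for c in range(3):
                        block = x[n, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2, c]
                        assert out[n, i, j, c] == block.max()

    def test_maxpool_backward_routes_gradient_to_argmax_only(self):
        rng = np.random.default_rng(4)
        pool = nn.MaxPool2d(2)
        x = rng.normal(size=(1, 4, 4, 2)).astype(np.float32)
        out = pool.forward(x)
        dout = np.ones_like(out)
        dx = pool.backward(dout)
        assert dx.sum() == pytest.approx(out.size)
        # gradient lands exactly on each block's maximum
        for i in range(2):
            for j in range(2):
                for c in range(2):
                    block = x[0, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2, c]
                    dblock = dx[0, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2, c]
                    assert dblock.flatten()[block.flatten().argmax()] == 1.0
                    assert dblock.sum() == 1.0

    def test_linear_gradients_match_closed_form(self):
        rng = np.random.default_rng(5)
        lin = nn.Linear(4, 3, rng=rng)
        x = rng.normal(size=(5, 4)).astype(np.float32)
        dout = rng.normal(size=(5, 3)).astype(np.float32)
        lin.forward(x)
        dx = lin.backward(dout)
        np.testing.assert_allclose(dx, dout @ lin.params["W"].T, atol=1e-5)
        np.testing.assert_allclose(lin.grads["W"], x.T @ dout, atol=1e-5)
        np.testing.assert_allclose(lin.grads["b"], dout.sum(axis=0), atol=1e-5)

    def test_dropout_is_identity_at_eval_and_unbiased_in_train(self):
        rng = np.random.default_rng(6)
        drop = nn.Dropout(0.4, rng=rng)
        x = np.ones((200, 50), np.float32)
        np.testing.assert_array_equal(drop.forward(x, train=False), x)
        y = drop.forward(x, train=True)
        # inverted scaling keeps the expectation near 1
        assert y.mean() == pytest.approx(1.0, abs=0.02)
        assert set(np.unique(y)).issubset({0.0, np.float32(1 / 0.6)})

    def test_dropout_rate_bounds(self):
        with pytest.raises(ValueError):
            nn.Dropout(1.0)


class TestLossAndOptimizer:
    def test_cross_entropy_matches_scipy_softmax(self):
        from scipy.special import log_softmax

        rng = np.random.default_rng(7)
        logits = rng.normal(size=(6, 2))
        labels = rng.integers(0, 2, size=6)
        loss, grad = nn.cross_entropy_with_grad(logits, labels)
        expect = -log_softmax(logits, axis=1)[np.arange(6), labels].mean()
        assert loss == pytest.approx(expect, rel=1e-9)

    def test_cross_entropy_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(8)
        logits = rng.normal(size=(4, 2))
        labels = rng.integers(0, 2, size=4)
        _, grad = nn.cross_entropy_with_grad(logits, labels)
        num = _numeric_grad(
            lambda: nn.cross_entropy_with_grad(logits, labels)[0], logits, eps=1e-5
        )
        assert _rel_err(grad, num) < 1e-5

    def test_adam_first_step_moves_param_by_lr(self):
        # with bias correction, the first step is lr * g / (|g| + eps)
        lin = nn.Linear(1, 1, rng=np.random.default_rng(9))
        net = nn.Network([("fc", lin)], tap_points=[])
        lin.params["W"][:] = 1.0
        lin.grads = {"W": np.array([[0.5]], np.float32),
                     "b": np.array([0.0], np.float32)}
        opt = nn.Adam(lr=0.1, weight_decay=0.0)
        opt.step(net)
        assert lin.params["W"][0, 0] == pytest.approx(1.0 - 0.1, abs=1e-5)

    def test_decoupled_weight_decay_only_shrinks_matrices(self):
        lin = nn.Linear(2, 2, rng=np.random.default_rng(10))
        net = nn.Network([("fc", lin)], tap_points=[])
        lin.params["W"][:] = 1.0
        lin.params["b"][:] = 1.0
        lin.grads = {"W": np.zeros((2, 2), np.float32), "b": np.zeros(2, np.float32)}
        opt = nn.Adam(lr=0.1, weight_decay=0.5)
        opt.step(net)
        assert lin.params["W"][0, 0] == pytest.approx(1.0 - 0.1 * 0.5 * 1.0)
        assert lin.params["b"][0] == pytest.approx(1.0)


class TestNetwork:
    def _tiny_net(self, seed=0):
        r = np.random.default_rng(seed)
        return nn.Network(
            [
                ("conv", nn.Conv2d(1, 2, 3, rng=r)),
                ("act", nn.ReLU()),
                ("pool", nn.MaxPool2d(2)),
                ("flat", nn.Flatten()),
                ("fc", nn.Linear(2 * 2 * 2, 2, rng=r)),
            ],
            tap_points=["act"],
        )

    def test_end_to_end_parameter_gradients_match_finite_differences(self):
        net = self._tiny_net()
        rng = np.random.default_rng(11)
        x = rng.normal(size=(3, 4, 4, 1)).astype(np.float32)
        labels = np.array([0, 1, 0])
        conv = dict(net.layers)["conv"]
        W64 = conv.params["W"].astype(np.float64)

        def loss():
            conv.params["W"] = W64.astype(np.float32)
            logits, _ = net.forward(x)
            return nn.cross_entropy_with_grad(logits, labels)[0]

        num = _numeric_grad(loss, W64, eps=1e-2)
        conv.params["W"] = W64.astype(np.float32)
        logits, _ = net.forward(x)
        _, dlogits = nn.cross_entropy_with_grad(logits, labels)
        net.backward(dlogits)
        assert _rel_err(conv.grads["W"], num) < 2e-2

    def test_taps_capture_activations_and_gradients(self):
        net = self._tiny_net()
        x = np.random.default_rng(12).normal(size=(2, 4, 4, 1)).astype(np.float32)
        logits, taps = net.forward(x, taps=["act"])
        assert taps["act"].shape == (2, 4, 4, 2)
        grads = net.backward(np.ones_like(logits), grad_taps=["act"])
        assert grads["act"].shape == taps["act"].shape
        with pytest.raises(KeyError):
            net.forward(x, taps=["nope"])

    def test_state_dict_roundtrip_through_npz(self, tmp_path):
        net = self._tiny_net(seed=1)
        path = tmp_path / "weights.npz"
        net.save(path)
        other = self._tiny_net(seed=99)
        other.load(path)
        x = np.random.default_rng(13).normal(size=(1, 4, 4, 1)).astype(np.float32)
        np.testing.assert_allclose(net.forward(x)[0], other.forward(x)[0], atol=1e-6)

    def test_duplicate_layer_names_and_bad_taps_are_rejected(self):
        with pytest.raises(ValueError):
            nn.Network([("a", nn.ReLU()), ("a", nn.ReLU())], tap_points=[])
        with pytest.raises(ValueError):
            nn.Network([("a", nn.ReLU())], tap_points=["b"])
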