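"""Numerical correctness of the 3D layer primitives.

Every layer's analytic backward pass is checked against central finite
differences of a random scalar objective on micro-sized tensors; geometry
helpers are checked against hand-computed ceil-mode arithmetic.
"""

import numpy as np
import pytest

from m3 import nn

RNG = np.random.default_rng(12345)


def _num_grad_param(layer, x, g, name, idx, eps=1e-3, train_mode=False):
    p = layer.params[name]
    orig = p[idx]
    p[idx] = orig + eps
    lp = float((layer.forward(x, retain=train_mode) * g).sum())
    p[idx] = orig - eps
    lm = float((layer.forward(x, retain=train_mode) * g).sum())
    p[idx] = orig
    return (lp - lm) / (2 * eps)


def _num_grad_input(layer, x, g, idx, eps=1e-3, train_mode=False):
    x2 = x.copy()
    x2[idx] += eps
    lp = float((layer.forward(x2, retain=train_mode) * g).sum())
    x2[idx] -= 2 * eps
    lm = float((layer.forward(x2, retain=train_mode) * g).sum())
    return (lp - lm) / (2 * eps)


def _check_layer_grads(layer, x, param_idxs=(), input_idxs=(), tol=5e-2,
                       train_mode=False):
    # train_mode: layers like batch norm behave differently outside training;
    # finite differences must then be taken through the training-mode forward
    out = layer.forward(x, retain=True)
    g = RNG.normal(size=out.shape).astype(np.float32)
    layer.zero_grad()
    dx = layer.backward(g)
    for name, idx in param_idxs:
        fd = _num_grad_param(layer, x, g, name, idx, train_mode=train_mode)
        an = float(layer.grads[name][idx])
        assert an == pytest.approx(fd, abs=tol + 0.02 * abs(fd))
    for idx in input_idxs:
        fd = _num_grad_input(layer, x, g, idx, train_mode=train_mode)
        assert float(dx[idx]) == pytest.approx(fd, abs=tol + 0.02 * abs(fd))


class TestGeometry:
    @pytest.mark.parametrize(
        "n,k,s,d,expected",
        [
            (155, 7, 2, 1, 78),  # stem on the full-scale depth axis
            (280, 7, 2, 1, 140),
            (78, 3, 2, 1, 39),  # max pooling
            (39, 3, 2, 1, 20),  # stage-2 stride
            (20, 3, 1, 2, 20),  # dilated stage keeps its grid
            (20, 3, 1, 4, 20),
        ],
    )
    def test_ceil_mode_output_lengths(self, n, k, s, d, expected):
        out, lo, hi = nn.same_geometry(n, k, s, d)
        assert out == expected
        eff = (k - 1) * d + 1
        assert lo + hi == max(0, (out - 1) * s + eff - n)


class TestConv3d:
    @pytest.mark.parametrize(
        "cin,cout,k,stride,dilation",
        [
            (1, 3, 7, 2, 1),  # stem-like (parity fast path)
            (3, 4, 3, 1, 1),
            (4, 2, 3, 2, 1),
            (2, 3, 3, 1, 2),  # dilated
            (5, 4, 1, 1, 1),  # pointwise
            (3, 4, 1, 2, 1),  # strided shortcut projection
        ],
    )
    def test_gradients_match_finite_differences(self, cin, cout, k, stride, dilation):
        conv = nn.Conv3d(cin, cout, k, stride=stride, dilation=dilation,
                         rng=np.random.default_rng(7))
        x = RNG.normal(size=(cin, 2, 9, 10, 11)).astype(np.float32)
        _check_layer_grads(
            conv,
            x,
            param_idxs=[("weight", (0, 0) + (min(k - 1, 2),) * 3),
                        ("weight", (cout - 1, cin - 1, 0, 0, 0))],
            input_idxs=[(0, 0, 4, 5, 6), (cin - 1, 1, 0, 0, 0)],
        )

    def test_inference_and_training_paths_agree(self):
        conv = nn.Conv3d(3, 4, 3, stride=2, rng=np.random.default_rng(8))
        x = RNG.normal(size=(3, 2, 8, 9, 10)).astype(np.float32)
        np.testing.assert_allclose(
            conv.forward(x, retain=True), conv.forward(x, retain=False), atol=1e-5
        )

    def test_parity_path_matches_direct_convolution(self):
        # stride-2 single-channel fast path vs explicit sliding window
        conv = nn.Conv3d(1, 2, 3, stride=2, rng=np.random.default_rng(9))
        x = RNG.normal(size=(1, 1, 6, 6, 6)).astype(np.float32)
        out = conv.forward(x)
        w = conv.params["weight"]
        # ceil-mode padding for n=6, k=3, s=2 is (0, 1): windows start at 2z
        xp = np.pad(x[0, 0], ((0, 1), (0, 1), (0, 1)))
        manual = np.zeros((2, 3, 3, 3), np.float32)
        for co in range(2):
            for z in range(3):
                for y in range(3):
                    for xx in range(3):
                        patch = xp[2 * z : 2 * z + 3, 2 * y : 2 * y + 3, 2 * xx : 2 * xx + 3]
                        manual[co, z, y, xx] = (w[co, 0] * patch).sum()
        np.testing.assert_allclose(out[:, 0], manual, atol=1e-5)


class TestNormPoolResize:
    def test_batch_norm_gradients(self):
        layer = nn.BatchNorm3d(3)
        layer.params["gamma"][:] = [1.3, 0.7, 1.1]
        layer.params["beta"][:] = [0.1, -0.2, 0.0]
        x = RNG.normal(size=(3, 2, 4, 5, 4)).astype(np.float32)
        _check_layer_grads(
            layer,
            x,
            param_idxs=[("gamma", (0,)), ("beta", (2,))],
            input_idxs=[(0, 0, 1, 2, 3), (2, 1, 0, 0, 0)],
            train_mode=True,
        )

    def test_batch_norm_training_standardizes_per_channel(self):
        layer = nn.BatchNorm3d(2)
        x = RNG.normal(2.0, 3.0, size=(2, 3, 6, 6, 6)).astype(np.float32)
        out = layer.forward(x, retain=True)
        assert np.abs(out.mean(axis=(1, 2, 3, 4))).max() < 1e-4
        assert np.abs(out.std(axis=(1, 2, 3, 4)) - 1).max() < 1e-3

    def test_batch_norm_inference_is_a_fixed_affine_map(self):
        # absolute scale must survive inference: doubling the input doubles
        # the centered output, unlike any per-sample normalization
        layer = nn.BatchNorm3d(1)
        for _ in range(200):  # converge the running statistics
            layer.forward(RNG.normal(1.0, 2.0, size=(1, 4, 5, 5, 5)).astype(np.float32),
                          retain=True)
        x = RNG.normal(1.0, 2.0, size=(1, 1, 5, 5, 5)).astype(np.float32)
        a = layer.forward(x)
        b = layer.forward(x + 1.0)
        np.testing.assert_allclose(b - a, (1.0 / np.sqrt(layer.running_var[0] + 1e-5)),
                                   atol=1e-4)

    def test_maxpool_gradients(self):
        pool = nn.MaxPool3d(3, 2)
        x = RNG.normal(size=(2, 2, 7, 8, 7)).astype(np.float32)
        _check_layer_grads(pool, x, input_idxs=[(0, 0, 3, 3, 3), (1, 1, 0, 0, 0)])

    def test_resize_constant_preserved_and_grads(self):
        resize = nn.TrilinearResize((5, 7, 6))
        const = np.full((2, 1, 3, 4, 3), 2.5, np.float32)
        np.testing.assert_allclose(resize.forward(const), 2.5, atol=1e-6)
        x = RNG.normal(size=(2, 1, 3, 4, 3)).astype(np.float32)
        _check_layer_grads(resize, x, input_idxs=[(0, 0, 1, 2, 1), (1, 0, 0, 0, 0)])


class TestLosses:
    def test_cross_entropy_gradient(self):
        logits = RNG.normal(size=(2, 2, 3, 4, 3)).astype(np.float32)
        target = (RNG.random((2, 3, 4, 3)) > 0.7).astype(np.float32)
        loss, grad = nn.softmax_cross_entropy(logits, target, pos_weight=3.0)
        eps = 1e-3
        for idx in [(0, 0, 1, 1, 1), (1, 1, 2, 3, 2)]:
            l2 = logits.copy()
            l2[idx] += eps
            lp, _ = nn.softmax_cross_entropy(l2, target, pos_weight=3.0)
            l2[idx] -= 2 * eps
            lm, _ = nn.softmax_cross_entropy(l2, target, pos_weight=3.0)
            assert float(grad[idx]) == pytest.approx((lp - lm) / (2 * eps), abs=1e-4)

    def test_dice_gradient_and_range(self):
        logits = RNG.normal(size=(2, 1, 4, 4, 4)).astype(np.float32)
        target = (RNG.random((1, 4, 4, 4)) > 0.5).astype(np.float32)
        loss, grad = nn.soft_dice_loss(logits, target)
        assert 0.0 <= loss <= 1.0
        eps = 1e-3
        for idx in [(0, 0, 0, 0, 0), (1, 0, 2, 2, 2)]:
            l2 = logits.copy()
            l2[idx] += eps
            lp, _ = nn.soft_dice_loss(l2, target)
            l2[idx] -= 2 * eps
            lm, _ = nn.soft_dice_loss(l2, target)
            assert float(grad[idx]) == pytest.approx((lp - lm) / (2 * eps), abs=1e-4)

    def test_equal_logits_give_half_probability(self):
        logits = np.ones((2, 1, 3, 3, 3), np.float32) * 4.2
        probs = nn.softmax2(logits)
        np.testing.assert_allclose(probs, 0.5, atol=1e-6)


class TestAdam:
    def test_converges_on_quadratic(self):
        params = {"w": np.array([5.0, -3.0])}
        opt = nn.Adam(lr=0.1)
        for _ in range(300):
            opt.step(params, {"w": 2 * params["w"]})
        assert np.abs(params["w"]).max() < 1e-2
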