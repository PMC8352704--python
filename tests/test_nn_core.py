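import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copdfusion import nn_core as nc


def brute_conv(x, kernels, biases, stride):
    """Four-deep nested-loop reference for valid cross-correlation."""
    out_c, in_c, k, _ = kernels.shape
    c, h, w = x.shape
    ph = (h - k) // stride + 1
    pw = (w - k) // stride + 1
    out = np.zeros((out_c, ph, pw))
    for o in range(out_c):
        for p in range(ph):
            for q in range(pw):
                acc = 0.0
                for ci in range(in_c):
                    for i in range(k):
                        for j in range(k):
                            acc += x[ci, p * stride + i, q * stride + j] * kernels[o, ci, i, j]
                out[o, p, q] = acc + biases[o]
    return out


def brute_pool(x, size, stride):
    c, h, w = x.shape
    ph = (h - size) // stride + 1
    pw = (w - size) // stride + 1
    out = np.zeros((c, ph, pw))
    for ci in range(c):
        for p in range(ph):
            for q in range(pw):
                tile = x[ci, p * stride : p * stride + size, q * stride : q * stride + size]
                out[ci, p, q] = tile.mean()
    return out


class TestConv2d:
    def test_identity_kernel(self, rng):
        x = rng.random((1, 5, 5))
        params = nc.ConvLayerParams(np.ones((1, 1, 1, 1)), np.zeros(1))
        np.testing.assert_array_equal(nc.conv2d_valid(x, params), x)

    def test_table_shape(self, rng):
        x = rng.random((1, 28, 28))
        params = nc.ConvLayerParams(rng.normal(size=(6, 1, 5, 5)), rng.normal(size=6))
        assert nc.conv2d_valid(x, params).shape == (6, 24, 24)

    def test_matches_brute_force_documented_case(self, rng):
        x = rng.normal(size=(3, 7, 7))
        params = nc.ConvLayerParams(rng.normal(size=(4, 3, 3, 3)), rng.normal(size=4))
        np.testing.assert_allclose(
            nc.conv2d_valid(x, params),
            brute_conv(x, params.kernels, params.biases, 1),
            atol=1e-12,
        )

    def test_matches_brute_force_randomized(self, rng):
        # >=100 random small instances against the nested-loop oracle
        for _ in range(100):
            in_c = int(rng.integers(1, 4))
            out_c = int(rng.integers(1, 4))
            k = int(rng.integers(1, 4))
            stride = int(rng.integers(1, 3))
            h = int(rng.integers(k, k + 5))
            w = int(rng.integers(k, k + 5))
            x = rng.normal(size=(in_c, h, w))
            params = nc.ConvLayerParams(
                rng.normal(size=(out_c, in_c, k, k)), rng.normal(size=out_c), stride
            )
            np.testing.assert_allclose(
                nc.conv2d_valid(x, params),
                brute_conv(x, params.kernels, params.biases, stride),
                atol=1e-10,
            )

    def test_kernel_larger_than_input_raises(self, rng):
        params = nc.ConvLayerParams(rng.normal(size=(1, 1, 5, 5)), np.zeros(1))
        with pytest.raises(ValueError):
            nc.conv2d_valid(rng.random((1, 3, 3)), params)


class TestAvgPool:
    def test_table_shape(self, rng):
        assert nc.avg_pool(rng.random((6, 24, 24)), 2, 2).shape == (6, 12, 12)

    def test_constant_map(self):
        x = np.full((2, 4, 4), 3.25)
        np.testing.assert_array_equal(nc.avg_pool(x, 2, 2), np.full((2, 2, 2), 3.25))

    def test_single_tile_mean(self):
        x = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        assert nc.avg_pool(x, 2, 2)[0, 0, 0] == 2.5

    def test_matches_brute_force_randomized(self, rng):
        for _ in range(100):
            c = int(rng.integers(1, 4))
            size = int(rng.integers(1, 4))
            stride = int(rng.integers(1, size + 1))
            n_tiles = int(rng.integers(1, 4))
            h = size + (n_tiles - 1) * stride
            x = rng.normal(size=(c, h, h))
            np.testing.assert_allclose(
                nc.avg_pool(x, size, stride), brute_pool(x, size, stride), atol=1e-12
            )

    def test_incomplete_tiles_raise(self, rng):
        with pytest.raises(ValueError):
            nc.avg_pool(rng.random((1, 5, 5)), 2, 2)

    def test_preserves_global_mean_on_exact_tiling(self, rng):
        x = rng.normal(size=(3, 8, 8))
        pooled = nc.avg_pool(x, 2, 2)
        np.testing.assert_allclose(pooled.mean(axis=(1, 2)), x.mean(axis=(1, 2)))


class TestSigmoid:
    def test_zero(self):
        assert nc.sigmoid(0.0) == 0.5

    @given(st.floats(-400, 400))
    @settings(max_examples=50, deadline=None)
    def test_complement_identity(self, x):
        assert nc.sigmoid(x) + nc.sigmoid(-x) == pytest.approx(1.0, abs=1e-12)

    def test_saturation_without_overflow(self):
        v = nc.sigmoid(-500.0)
        assert 0.0 <= v <= 1e-200
        assert nc.sigmoid(500.0) <= 1.0

    def test_range_open_interval(self, rng):
        v = nc.sigmoid(rng.normal(size=100) * 10)
        assert np.all((v > 0) & (v < 1))


class TestDense:
    def test_zero_weights_give_bias(self, rng):
        params = nc.DenseLayerParams(np.zeros((3, 5)), np.array([1.0, -2.0, 0.5]))
        np.testing.assert_array_equal(
            nc.dense_forward(rng.random(5), params), params.biases
        )

    def test_identity(self, rng):
        x = rng.random(4)
        params = nc.DenseLayerParams(np.eye(4), np.zeros(4))
        np.testing.assert_array_equal(nc.dense_forward(x, params), x)

    def test_matches_elementwise_oracle(self, rng):
        w = rng.normal(size=(3, 5))
        b = rng.normal(size=3)
        x = rng.normal(size=5)
        expected = np.array([sum(w[i, j] * x[j] for j in range(5)) + b[i] for i in range(3)])
        np.testing.assert_allclose(
            nc.dense_forward(x, nc.DenseLayerParams(w, b)), expected, atol=1e-12
        )

    def test_dimension_mismatch(self, rng):
        params = nc.DenseLayerParams(rng.normal(size=(3, 5)), np.zeros(3))
        with pytest.raises(ValueError):
            nc.dense_forward(rng.random(4), params)


class TestSoftmaxXent:
    def test_uniform_logits(self):
        p, loss = nc.softmax_xent(np.zeros(4), 2)
        np.testing.assert_allclose(p, 0.25)
        assert loss == pytest.approx(np.log(4))

    def test_saturated(self):
        p, _ = nc.softmax_xent(np.array([500.0, 0.0]), 0)
        np.testing.assert_allclose(p, [1.0, 0.0], atol=1e-12)

    def test_shift_invariance(self, rng):
        z = rng.normal(size=5)
        p1, l1 = nc.softmax_xent(z, 3)
        p2, l2 = nc.softmax_xent(z + 17.3, 3)
        np.testing.assert_allclose(p1, p2, atol=1e-12)
        assert l1 == pytest.approx(l2, abs=1e-10)

    def test_probabilities_sum_to_one(self, rng):
        for _ in range(20):
            p, loss = nc.softmax_xent(rng.normal(size=6) * 10, 0)
            assert abs(p.sum() - 1.0) < 1e-12
            assert loss >= 0

    def test_label_out_of_range(self):
        with pytest.raises(ValueError):
            nc.softmax_xent(np.zeros(3), 3)


class TestBackward:
    """Central finite differences (h=1e-5) vs analytic gradients."""

    @staticmethod
    def _rel_err(a, b):
        return np.abs(a - b) / np.maximum(1e-8, np.abs(a) + np.abs(b))

    def test_toy_network_all_layers(self, rng):
        # 1x8x8 -> conv(2, 3x3) -> sigmoid -> pool2 -> dense -> softmax loss
        x = rng.normal(size=(2, 1, 8, 8))
        y = np.array([0, 1])
        conv = nc.Conv2D(nc.ConvLayerParams(rng.normal(size=(2, 1, 3, 3)) * 0.5, rng.normal(size=2) * 0.1))
        layers = [
            conv,
            nc.SigmoidLayer(),
            nc.AvgPool(2, 2),
            nc.Flatten(),
            nc.Dense(nc.DenseLayerParams(rng.normal(size=(2, 18)) * 0.5, rng.normal(size=2) * 0.1)),
        ]

        def loss():
            z = x
            for layer in layers:
                z = layer.forward(z)
            return nc.softmax_xent_batch(z, y)[1]

        z = x
        for layer in layers:
            z = layer.forward(z)
        _, _, g = nc.softmax_xent_batch(z, y)
        gx = g
        for layer in reversed(layers):
            gx = layer.backward(gx)

        dense = layers[-1]
        checks = [
            (conv.d_kernels, conv.p.kernels),
            (conv.d_biases, conv.p.biases),
            (dense.d_weights, dense.p.weights),
            (dense.d_biases, dense.p.biases),
        ]
        for analytic, param in checks:
            fd = nc.finite_difference_grad(loss, param, h=1e-5)
            assert self._rel_err(analytic, fd).max() <= 1e-4
        fd_x = nc.finite_difference_grad(loss, x, h=1e-5)
        assert self._rel_err(gx, fd_x).max() <= 1e-4

    def test_zero_upstream_gives_zero_parameter_grads(self, rng):
        conv = nc.Conv2D(nc.ConvLayerParams(rng.normal(size=(2, 1, 3, 3)), rng.normal(size=2)))
        out = conv.forward(rng.normal(size=(1, 1, 6, 6)))
        conv.backward(np.zeros_like(out))
        assert np.all(conv.d_kernels == 0)
        assert np.all(conv.d_biases == 0)

    def test_sigmoid_slope_at_zero(self):
        sig = nc.SigmoidLayer()
        sig.forward(np.zeros((1, 1)))
        np.testing.assert_allclose(sig.backward(np.ones((1, 1))), 0.25)

    def test_backward_before_forward_raises(self):
        with pytest.raises(RuntimeError):
            nc.SigmoidLayer().backward(np.ones((1, 1)))

    def test_strided_conv_gradients(self, rng):
        x = rng.normal(size=(2, 2, 7, 7))
        conv = nc.Conv2D(nc.ConvLayerParams(rng.normal(size=(3, 2, 3, 3)), rng.normal(size=3), stride=2))
        g = rng.normal(size=conv.forward(x).shape)
        dx = conv.backward(g)

        def weighted_out():
            return float((conv.forward(x) * g).sum())

        fd_k = nc.finite_difference_grad(weighted_out, conv.p.kernels, h=1e-5)
        fd_x = nc.finite_difference_grad(weighted_out, x, h=1e-5)
        assert self._rel_err(conv.d_kernels, fd_k).max() <= 1e-4
        assert self._rel_err(dx, fd_x).max() <= 1e-4
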