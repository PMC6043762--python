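"""Convolution, pooling, batch norm and ReLU: forward oracles, exact
gradients, and the adjoint structure of mean pooling."""

import numpy as np
import pytest

from spherecnn.icosphere import icosphere, pooling_map
from spherecnn.layers import (
    BatchNormLayer,
    ConvFilterBank,
    DenseLayer,
    MeshConvLayer,
    MeshPoolLayer,
    ReLULayer,
    mesh_conv_backward,
    mesh_conv_forward,
    mesh_pool_backward,
    mesh_pool_forward,
    relu,
)
from spherecnn.patch_sampling import (
    build_sampling_map,
    polygonal_neighbors,
    rectangular_template,
    sample,
)


@pytest.fixture(scope="module")
def mesh1():
    return icosphere(1)


@pytest.fixture(scope="module")
def pm10(mesh1):
    return pooling_map(mesh1, icosphere(0))


def brute_force_conv(I, weights, bias):
    """Nested-loop oracle for O[n, f] = sum_pc I[n,p,c] W[f,p,c] + b[f]."""
    n, p, c = I.shape
    fb = weights.shape[0]
    out = np.zeros((n, fb))
    for i in range(n):
        for f in range(fb):
            acc = 0.0
            for q in range(p):
                for ch in range(c):
                    acc += I[i, q, ch] * weights[f, q * c + ch]
            out[i, f] = acc + bias[f]
    return out


class TestConvForward:
    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(3)
        I = rng.standard_normal((42, 25, 1))
        bank = ConvFilterBank(rng.standard_normal((3, 25)), rng.standard_normal(3))
        out = mesh_conv_forward(I, bank)
        assert np.allclose(out, brute_force_conv(I, bank.weights, bank.bias), atol=1e-10)

    def test_two_channel_oracle(self):
        rng = np.random.default_rng(4)
        I = rng.standard_normal((12, 9, 2))
        bank = ConvFilterBank(rng.standard_normal((5, 18)), rng.standard_normal(5))
        out = mesh_conv_forward(I, bank)
        assert np.allclose(out, brute_force_conv(I, bank.weights, bank.bias), atol=1e-10)

    def test_identity_filter_recovers_input(self, mesh1):
        # one-hot weight on point 0 (the node itself) copies the map through
        sm = build_sampling_map(rectangular_template(3, 3, 0.3), mesh1)
        v = np.random.default_rng(0).standard_normal(42)
        I = sample(sm, v)
        w = np.zeros((1, 9))
        w[0, 0] = 1.0
        out = mesh_conv_forward(I, ConvFilterBank(w, np.zeros(1)))
        assert np.allclose(out[:, 0], v)

    def test_zero_weights_zero_output(self):
        I = np.random.default_rng(1).standard_normal((42, 25, 1))
        out = mesh_conv_forward(I, ConvFilterBank(np.zeros((2, 25)), np.zeros(2)))
        assert np.all(out == 0)

    def test_sliding_patch_oracle_across_levels(self):
        # per-node patch dot product equals the reshaped matrix product
        rng = np.random.default_rng(7)
        for level in (0, 1, 2):
            mesh = icosphere(level)
            sm = build_sampling_map(
                rectangular_template(3, 3, mesh.mean_edge_angle()), mesh
            )
            v = rng.standard_normal(mesh.n_nodes)
            I = sample(sm, v)
            bank = ConvFilterBank(rng.standard_normal((2, 9)), rng.standard_normal(2))
            out = mesh_conv_forward(I, bank)
            for n in (0, mesh.n_nodes // 2):
                patch = v[sm.index[n]]
                for f in range(2):
                    assert np.isclose(out[n, f], patch @ bank.weights[f] + bank.bias[f])

    def test_dimension_mismatch(self):
        I = np.zeros((10, 9, 1))
        with pytest.raises(ValueError):
            mesh_conv_forward(I, ConvFilterBank(np.zeros((2, 25)), np.zeros(2)))


class TestConvBackward:
    def test_finite_difference(self, mesh1):
        rng = np.random.default_rng(5)
        sm = build_sampling_map(rectangular_template(3, 3, 0.3), mesh1)
        I = sample(sm, rng.standard_normal((42, 2)))
        bank = ConvFilterBank(rng.standard_normal((3, 18)), rng.standard_normal(3))
        g = rng.standard_normal((42, 3))
        grad_I, grad_W, grad_b = mesh_conv_backward(g, I, bank)

        def loss(values, weights, bias):
            return np.sum(
                mesh_conv_forward(
                    type(I)(values=values, provenance=sm), ConvFilterBank(weights, bias)
                )
                * g
            )

        eps = 1e-6
        for arr, grad, args in [
            (I.values, grad_I, 0),
            (bank.weights, grad_W, 1),
            (bank.bias, grad_b, 2),
        ]:
            flat = arr.ravel()
            for k in rng.choice(flat.size, size=min(8, flat.size), replace=False):
                flat[k] += eps
                up = loss(I.values, bank.weights, bank.bias)
                flat[k] -= 2 * eps
                dn = loss(I.values, bank.weights, bank.bias)
                flat[k] += eps
                num = (up - dn) / (2 * eps)
                assert np.isclose(num, grad.ravel()[k], rtol=1e-5, atol=1e-7)

    def test_grad_bias_is_column_sums(self):
        rng = np.random.default_rng(6)
        I = rng.standard_normal((12, 4, 1))
        bank = ConvFilterBank(rng.standard_normal((3, 4)), np.zeros(3))
        g = rng.standard_normal((12, 3))
        _, _, grad_b = mesh_conv_backward(g, I, bank)
        assert np.allclose(grad_b, g.sum(axis=0))

    def test_zero_gradient(self):
        I = np.random.default_rng(0).standard_normal((12, 4, 1))
        bank = ConvFilterBank(np.ones((3, 4)), np.zeros(3))
        grad_I, grad_W, grad_b = mesh_conv_backward(np.zeros((12, 3)), I, bank)
        assert not grad_I.any() and not grad_W.any() and not grad_b.any()

    def test_padded_points_receive_no_gradient(self, mesh1):
        sm = polygonal_neighbors(mesh1, 1)  # 12 degree-5 rows are padded
        assert sm.has_padding
        I = sample(sm, np.random.default_rng(2).standard_normal(42))
        bank = ConvFilterBank(np.ones((1, sm.n_points)), np.zeros(1))
        grad_I, _, _ = mesh_conv_backward(np.ones((42, 1)), I, bank)
        assert np.all(grad_I[sm.index == sm.sentinel] == 0)


class TestPooling:
    def test_constant_preserved_at_every_level(self):
        for fine_level in (1, 2, 3):
            pm = pooling_map(icosphere(fine_level), icosphere(fine_level - 1))
            out = mesh_pool_forward(np.full((pm.n_fine, 3), 2.5), pm)
            assert np.allclose(out, 2.5)

    def test_mean_over_enumerated_children(self, mesh1, pm10):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((42, 2))
        out = mesh_pool_forward(x, pm10)
        for c, ch in enumerate(pm10.children):
            assert np.allclose(out[c], x[list(ch)].mean(axis=0))

    def test_backward_is_adjoint(self, pm10):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((42, 3))
        y = rng.standard_normal((12, 3))
        lhs = np.sum(mesh_pool_forward(x, pm10) * y)
        rhs = np.sum(x * mesh_pool_backward(y, pm10))
        assert np.isclose(lhs, rhs, atol=1e-12)

    def test_one_hot_distributes_equally(self, pm10):
        g = np.zeros((12, 1))
        g[4] = 1.0
        fine = mesh_pool_backward(g, pm10)
        ch = pm10.children[4]
        assert np.allclose(fine[list(ch), 0], 1.0 / len(ch))
        mask = np.ones(42, dtype=bool)
        mask[list(ch)] = False
        assert not fine[mask].any()

    def test_backward_finite_difference(self, pm10):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((42, 2))
        g = rng.standard_normal((12, 2))
        grad = mesh_pool_backward(g, pm10)
        eps = 1e-6
        for k in rng.choice(x.size, size=10, replace=False):
            x.ravel()[k] += eps
            up = np.sum(mesh_pool_forward(x, pm10) * g)
            x.ravel()[k] -= 2 * eps
            dn = np.sum(mesh_pool_forward(x, pm10) * g)
            x.ravel()[k] += eps
            assert np.isclose((up - dn) / (2 * eps), grad.ravel()[k], rtol=1e-6, atol=1e-9)

    def test_level_mismatch_rejected(self, pm10):
        with pytest.raises(ValueError):
            mesh_pool_forward(np.zeros((162, 1)), pm10)

    def test_max_pool_backward_routes_to_argmax(self, mesh1, pm10):
        layer = MeshPoolLayer(pm10, mode="max")
        rng = np.random.default_rng(11)
        x = rng.standard_normal((2, 42, 3))
        out = layer.forward(x, train=True)
        g = rng.standard_normal(out.shape)
        grad = layer.backward(g)
        # numerical check on a few coordinates
        eps = 1e-6
        for k in rng.choice(x.size, size=8, replace=False):
            x.ravel()[k] += eps
            up = np.sum(layer.forward(x, train=True) * g)
            x.ravel()[k] -= 2 * eps
            dn = np.sum(layer.forward(x, train=True) * g)
            x.ravel()[k] += eps
            assert np.isclose((up - dn) / (2 * eps), grad.ravel()[k], rtol=1e-4, atol=1e-8)


class TestBatchNorm:
    def test_training_standardizes(self):
        bn = BatchNormLayer(3)
        x = np.random.default_rng(0).standard_normal((8, 10, 3)) * 4 + 2
        out = bn.forward(x, train=True)
        assert np.allclose(out.mean(axis=(0, 1)), 0.0, atol=1e-10)
        assert np.allclose(out.var(axis=(0, 1)), 1.0, atol=1e-3)

    def test_inference_deterministic(self):
        bn = BatchNormLayer(2)
        rng = np.random.default_rng(1)
        for _ in range(5):
            bn.forward(rng.standard_normal((6, 4, 2)), train=True)
        x = rng.standard_normal((3, 4, 2))
        assert np.array_equal(bn.forward(x, train=False), bn.forward(x, train=False))

    def test_batch_of_one_rejected(self):
        bn = BatchNormLayer(2)
        with pytest.raises(ValueError):
            bn.forward(np.zeros((1, 1, 2)), train=True)

    def test_backward_finite_difference(self):
        bn = BatchNormLayer(2)
        rng = np.random.default_rng(2)
        x = rng.standard_normal((5, 3, 2))
        g = rng.standard_normal((5, 3, 2))
        bn.forward(x, train=True)
        grad = bn.backward(g)
        eps = 1e-6
        for k in rng.choice(x.size, size=8, replace=False):
            x.ravel()[k] += eps
            up = np.sum(bn.forward(x, train=True) * g)
            x.ravel()[k] -= 2 * eps
            dn = np.sum(bn.forward(x, train=True) * g)
            x.ravel()[k] += eps
            assert np.isclose((up - dn) / (2 * eps), grad.ravel()[k], rtol=1e-4, atol=1e-8)


class TestReLU:
    def test_values(self):
        assert np.array_equal(relu(np.array([-1.0, 0.0, 2.0])), [0.0, 0.0, 2.0])

    def test_gradient_mask(self):
        layer = ReLULayer()
        x = np.array([[-2.0, 0.0, 3.0]])
        layer.forward(x, train=True)
        g = layer.backward(np.ones_like(x))
        assert np.array_equal(g, [[0.0, 0.0, 1.0]])


class TestLayerVsFunctional:
    def test_conv_layer_matches_functional(self, mesh1):
        # the batched layer and the (sample -> I x W) pipeline agree exactly
        rng = np.random.default_rng(12)
        sm = build_sampling_map(rectangular_template(3, 3, 0.3), mesh1)
        layer = MeshConvLayer(sm, in_channels=2, out_channels=4, rng=rng)
        x = rng.standard_normal((3, 42, 2))
        out = layer.forward(x, train=True)
        w = layer.params["W"]
        bank = ConvFilterBank(w.T, layer.params["b"])
        for b in range(3):
            I = sample(sm, x[b])
            assert np.allclose(out[b], mesh_conv_forward(I, bank), atol=1e-12)

    def test_conv_layer_scatter_matches_dense_grad(self, mesh1):
        rng = np.random.default_rng(13)
        sm = polygonal_neighbors(mesh1, 1)
        layer = MeshConvLayer(sm, in_channels=1, out_channels=2, rng=rng)
        x = rng.standard_normal((2, 42, 1))
        out = layer.forward(x, train=True)
        g = rng.standard_normal(out.shape)
        grad = layer.backward(g)
        eps = 1e-6
        for k in rng.choice(x.size, size=8, replace=False):
            x.ravel()[k] += eps
            up = np.sum(layer.forward(x, train=True) * g)
            x.ravel()[k] -= 2 * eps
            dn = np.sum(layer.forward(x, train=True) * g)
            x.ravel()[k] += eps
            assert np.isclose((up - dn) / (2 * eps), grad.ravel()[k], rtol=1e-5, atol=1e-9)

    def test_dense_gradients(self):
        rng = np.random.default_rng(14)
        layer = DenseLayer(6, 3, rng)
        x = rng.standard_normal((4, 6))
        g = rng.standard_normal((4, 3))
        layer.forward(x, train=True)
        layer.backward(g)
        assert np.allclose(layer.grads["W"], x.T @ g)
        assert np.allclose(layer.grads["b"], g.sum(axis=0))
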