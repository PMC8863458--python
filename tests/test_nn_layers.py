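"""The numpy CNN engine: depthwise-separable oracle, gradients, invariants."""

import numpy as np
import pytest

from eegfusion.nn import (
    Adam,
    BatchNorm,
    Conv1d,
    Conv2d,
    Dense,
    DepthwiseConv,
    DepthwiseSeparableConv,
    GlobalAvgPool,
    MaxPool,
    PointwiseConv,
    softmax,
)


def depthwise_separable_oracle(x, dw_kernels, pw_kernels):
    """Direct two-stage summation: per-channel conv then 1x1 channel mixing.

    ``x`` is (C, B, L); ``dw_kernels`` (C, k); ``pw_kernels`` (C_out, C).
    Same zero padding, stride 1.
    """
    C, B, L = x.shape
    k = dw_kernels.shape[1]
    p = k // 2
    depth = np.zeros_like(x, dtype=np.float64)
    xp = np.pad(x.astype(np.float64), ((0, 0), (0, 0), (p, p)))
    for c in range(C):
        for b in range(B):
            for n in range(L):
                depth[c, b, n] = sum(
                    dw_kernels[c, i] * xp[c, b, n + i] for i in range(k)
                )
    out = np.zeros((pw_kernels.shape[0], B, L))
    for m in range(pw_kernels.shape[0]):
        for c in range(C):
            out[m] += pw_kernels[m, c] * depth[c]
    return out


class TestDepthwiseSeparable:
    def test_matches_direct_summation_oracle(self, rng):
        x = rng.standard_normal((3, 2, 8)).astype(np.float32)
        layer = DepthwiseSeparableConv(3, 5, (3,), rng)
        got = layer.forward(x, training=False)
        want = depthwise_separable_oracle(
            x, layer.depthwise.w.value, layer.pointwise.w.value
        )
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_identity_kernels_pass_input_through(self, rng):
        x = rng.standard_normal((4, 2, 10)).astype(np.float32)
        layer = DepthwiseSeparableConv(4, 4, (3,), rng)
        layer.depthwise.w.value[:] = 0.0
        layer.depthwise.w.value[:, 1] = 1.0  # unit impulse at center tap
        layer.pointwise.w.value[:] = np.eye(4, dtype=np.float32)
        np.testing.assert_allclose(layer.forward(x, False), x, atol=1e-6)

    def test_parameter_counts_16_to_32(self, rng):
        sep = DepthwiseSeparableConv(16, 32, (3,), rng)
        std = Conv1d(16, 32, 3, rng)
        n_sep = sum(p.size for p in sep.params())
        n_std = sum(p.size for p in std.params())
        assert n_sep == 16 * 3 + 16 * 32 == 560
        assert n_std == 16 * 3 * 32 == 1536
        assert n_sep < n_std


def _numeric_param_grads(layer, x, eps=1e-3, max_checks=25):
    """Subsampled central-difference gradients of L = sum(out^2)/2."""

    def loss():
        out = layer.forward(x, training=True)
        return float(np.sum(out.astype(np.float64) ** 2) / 2)

    out = layer.forward(x, training=True)
    layer.backward(out.astype(np.float32).copy())
    check_rng = np.random.default_rng(0)
    for p in layer.params():
        flat = p.value.ravel()
        idxs = check_rng.choice(flat.size, size=min(max_checks, flat.size), replace=False)
        for i in idxs:
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss()
            flat[i] = orig - eps
            lm = loss()
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            ana = p.grad.ravel()[i]
            assert abs(num - ana) <= 5e-2 * max(1.0, abs(num)), (p.name, i, num, ana)


@pytest.mark.parametrize(
    "factory,shape",
    [
        (lambda rng: Conv1d(3, 4, 5, rng), (3, 2, 16)),
        (lambda rng: Conv2d(2, 3, (3, 5), rng), (2, 2, 7, 9)),
        (lambda rng: DepthwiseConv(3, (3,), rng), (3, 2, 16)),
        (lambda rng: DepthwiseSeparableConv(2, 4, (3, 1), rng), (2, 2, 7, 9)),
        (lambda rng: PointwiseConv(3, 5, rng), (3, 2, 16)),
        (lambda rng: Dense(6, 3, rng), (4, 6)),
    ],
    ids=["conv1d", "conv2d", "depthwise", "separable2d", "pointwise", "dense"],
)
def test_backprop_matches_finite_differences(factory, shape, rng):
    layer = factory(rng)
    for p in layer.params():
        p.value[:] = rng.uniform(0.3, 1.3, p.value.shape).astype(np.float32)
    x = rng.standard_normal(shape).astype(np.float32)
    _numeric_param_grads(layer, x)


def test_batchnorm_backprop(rng):
    bn = BatchNorm(3)
    bn.gamma.value[:] = rng.uniform(0.5, 1.5, 3).astype(np.float32)
    bn.beta.value[:] = rng.uniform(-1.0, 1.0, 3).astype(np.float32)
    _numeric_param_grads(bn, rng.standard_normal((3, 2, 16)).astype(np.float32))


def test_batchnorm_eval_is_per_sample(rng):
    """In eval mode, outputs are independent of batch composition."""
    bn = BatchNorm(4)
    bn.forward(rng.standard_normal((4, 8, 20)).astype(np.float32), training=True)
    x = rng.standard_normal((4, 5, 20)).astype(np.float32)
    full = bn.forward(x, training=False)
    single = bn.forward(x[:, 2:3], training=False)
    np.testing.assert_allclose(full[:, 2:3], single, rtol=1e-6)


def test_maxpool_input_gradient(rng):
    pool = MaxPool()
    x = rng.standard_normal((2, 2, 6, 8)).astype(np.float32)
    out = pool.forward(x, training=True)
    dx = pool.backward(np.ones_like(out))
    # gradient mass is conserved and lands only on maxima
    assert dx.sum() == pytest.approx(out.size)
    assert set(np.unique(dx)) <= {0.0, 1.0}


def test_global_avg_pool_feature_dim(rng):
    gap = GlobalAvgPool()
    out = gap.forward(rng.standard_normal((32, 5, 7, 3)).astype(np.float32), False)
    assert out.shape == (5, 32)


def test_softmax_properties(rng):
    logits = rng.standard_normal((20, 2)) * 10
    p = softmax(logits)
    assert np.all(p > 0) and np.all(p < 1)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)


def test_adam_reduces_quadratic_loss(rng):
    from eegfusion.nn import Param

    p = Param("w", rng.standard_normal(10).astype(np.float32), True)
    opt = Adam([p])
    for _ in range(200):
        p.grad = 2 * p.value  # d/dw of sum(w^2)
        opt.step(0.05)
    assert float(np.sum(p.value**2)) < 1e-4
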