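"""Minimal CNN layer zoo with manual backpropagation.

All feature tensors use a channel-first layout ``(C, B, *spatial)`` — channels
outermost, batch second.  That makes every convolution a single GEMM of the
form ``W (C_out, k) @ cols (k, B*spatial)`` with no transposes on the hot
path, which is what keeps the large first spectrogram layer fast on one CPU
core.  Arithmetic is float32 throughout.

Layers implement ``forward(x, training)`` and ``backward(grad)``; ``backward``
returns the gradient with respect to the layer input, except for layers
constructed with ``first_layer=True`` whose input is the data itself (the
input gradient is skipped there to save the most expensive col2im).
"""

from __future__ import annotations

import numpy as np

from .._errors import ConfigurationError

DTYPE = np.float32


class Param:
    """A trainable array plus its gradient slot.

    ``regularized`` marks parameters included in the l2 penalty (convolution
    and dense weights); batch-norm scale/shift and biases are exempt.
    """

    __slots__ = ("name", "value", "grad", "regularized")

    def __init__(self, name: str, value: np.ndarray, regularized: bool) -> None:
        self.name = name
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.regularized = regularized

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    """Base layer: no parameters, identity bookkeeping."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray | None:  # pragma: no cover
        raise NotImplementedError


def _he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


# ---------------------------------------------------------------------------
# convolutions
# ---------------------------------------------------------------------------

def _pad_spatial(x: np.ndarray, pads: tuple[int, ...]) -> np.ndarray:
    """Zero-pad the trailing spatial axes of a (C, B, *spatial) tensor."""
    width = [(0, 0), (0, 0)] + [(p, p) for p in pads]
    return np.pad(x, width)


class Conv1d(Layer):
    """Standard 1-D convolution ('same' padding, stride 1, no bias)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        first_layer: bool = False,
        name: str = "conv1d",
    ) -> None:
        if kernel_size % 2 == 0:
            raise ConfigurationError("odd kernel sizes required for 'same' padding")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        self.first_layer = first_layer
        fan_in = in_channels * kernel_size
        self.w = Param(name + ".w", _he_uniform(rng, (out_channels, fan_in), fan_in), True)
        self._cols: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        C, B, L = x.shape
        p = self.k // 2
        xp = _pad_spatial(x, (p,))
        cols = np.empty((C * self.k, B * L), DTYPE)
        view = cols.reshape(C, self.k, B, L)
        for c in range(C):
            for i in range(self.k):
                view[c, i] = xp[c, :, i : i + L]
        return cols

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        C, B, L = x.shape
        cols = self._im2col(x)
        if training:
            self._cols = cols
            self._in_shape = x.shape
        return (self.w.value @ cols).reshape(self.cout, B, L)

    def backward(self, grad: np.ndarray) -> np.ndarray | None:
        CO, B, L = grad.shape
        gm = grad.reshape(CO, B * L)
        self.w.grad = gm @ self._cols.T
        self._cols = None
        if self.first_layer:
            return None
        # input gradient: convolution of grad with the flipped kernel
        C, k, p = self.cin, self.k, self.k // 2
        gw = self.w.value.reshape(CO, C, k)
        gp = _pad_spatial(grad, (p,))
        dx = np.zeros(self._in_shape, DTYPE)
        for c in range(C):
            for i in range(k):
                # dx[c, m] += sum_o w[o, c, i] * grad[o, m - i + p]
                seg = gp[:, :, k - 1 - i : k - 1 - i + L]
                dx[c] += np.tensordot(gw[:, c, i], seg, axes=(0, 0))
        return dx


class Conv2d(Layer):
    """Standard 2-D convolution ('same' padding, stride 1, no bias)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: tuple[int, int],
        rng: np.random.Generator,
        first_layer: bool = False,
        name: str = "conv2d",
    ) -> None:
        kh, kw = kernel_size
        if kh % 2 == 0 or kw % 2 == 0:
            raise ConfigurationError("odd kernel sizes required for 'same' padding")
        self.cin, self.cout, self.kh, self.kw = in_channels, out_channels, kh, kw
        self.first_layer = first_layer
        fan_in = in_channels * kh * kw
        self.w = Param(name + ".w", _he_uniform(rng, (out_channels, fan_in), fan_in), True)
        self._cols: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        C, B, H, W = x.shape
        ph, pw = self.kh // 2, self.kw // 2
        xp = _pad_spatial(x, (ph, pw))
        n = B * H * W
        if getattr(self, "_colbuf", None) is None or self._colbuf.shape[1] != n:
            self._colbuf = np.empty((C * self.kh * self.kw, n), DTYPE)
        cols = self._colbuf
        view = cols.reshape(C, self.kh, self.kw, B, H, W)
        for c in range(C):
            for i in range(self.kh):
                for j in range(self.kw):
                    view[c, i, j] = xp[c, :, i : i + H, j : j + W]
        return cols

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        C, B, H, W = x.shape
        cols = self._im2col(x)
        if training:
            self._cols = cols
            self._in_shape = x.shape
        return (self.w.value @ cols).reshape(self.cout, B, H, W)

    def backward(self, grad: np.ndarray) -> np.ndarray | None:
        CO, B, H, W = grad.shape
        gm = grad.reshape(CO, B * H * W)
        self.w.grad = gm @ self._cols.T
        self._cols = None
        if self.first_layer:
            return None
        C, kh, kw = self.cin, self.kh, self.kw
        gw = self.w.value.reshape(CO, C, kh, kw)
        gp = _pad_spatial(grad, (kh // 2, kw // 2))
        dx = np.zeros(self._in_shape, DTYPE)
        for c in range(C):
            for i in range(kh):
                for j in range(kw):
                    seg = gp[:, :, kh - 1 - i : kh - 1 - i + H, kw - 1 - j : kw - 1 - j + W]
                    dx[c] += np.tensordot(gw[:, c, i, j], seg, axes=(0, 0))
        return dx


class DepthwiseConv(Layer):
    """Depthwise stage: one small kernel per input channel, 'same' padding.

    Works for 1-D inputs ``(C, B, L)`` with kernel ``(k,)`` and 2-D inputs
    ``(C, B, H, W)`` with kernel ``(kh, kw)``.  This is the grouped first
    stage of the depthwise-separable convolution.
    """

    def __init__(
        self,
        channels: int,
        kernel_size: tuple[int, ...],
        rng: np.random.Generator,
        name: str = "dwconv",
    ) -> None:
        if any(k % 2 == 0 for k in kernel_size):
            raise ConfigurationError("odd kernel sizes required for 'same' padding")
        self.channels = channels
        self.kernel_size = tuple(kernel_size)
        fan_in = int(np.prod(kernel_size))
        self.w = Param(
            name + ".w", _he_uniform(rng, (channels,) + self.kernel_size, fan_in), True
        )

    def params(self) -> list[Param]:
        return [self.w]

    def _offsets(self):
        if len(self.kernel_size) == 1:
            return [(i,) for i in range(self.kernel_size[0])]
        kh, kw = self.kernel_size
        return [(i, j) for i in range(kh) for j in range(kw)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.shape[0] != self.channels:
            raise ConfigurationError(
                f"depthwise layer expects {self.channels} channels, got {x.shape[0]}"
            )
        pads = tuple(k // 2 for k in self.kernel_size)
        xp = _pad_spatial(x, pads)
        if training:
            self._xp = xp
            self._in_shape = x.shape
        spatial = x.shape[2:]
        out = np.zeros_like(x)
        for off in self._offsets():
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(off, spatial)
            )
            wsel = self.w.value[(slice(None),) + off]
            out += wsel.reshape((-1,) + (1,) * (x.ndim - 1)) * xp[sl]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        spatial = self._in_shape[2:]
        sum_axes = tuple(range(1, grad.ndim))
        dw = np.empty_like(self.w.value)
        for off in self._offsets():
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(off, spatial)
            )
            dw[(slice(None),) + off] = (grad * self._xp[sl]).sum(axis=sum_axes)
        self.w.grad = dw
        # input gradient: correlate grad with flipped kernel
        pads = tuple(k // 2 for k in self.kernel_size)
        gp = _pad_spatial(grad, pads)
        dx = np.zeros(self._in_shape, DTYPE)
        for off in self._offsets():
            flipped = tuple(k - 1 - o for k, o in zip(self.kernel_size, off))
            sl = (slice(None), slice(None)) + tuple(
                slice(f, f + s) for f, s in zip(flipped, spatial)
            )
            wsel = self.w.value[(slice(None),) + off]
            dx += wsel.reshape((-1,) + (1,) * (grad.ndim - 1)) * gp[sl]
        self._xp = None
        return dx


class PointwiseConv(Layer):
    """1x1 cross-channel mixing: the second stage of depthwise separable."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator,
        name: str = "pwconv",
    ) -> None:
        self.cin, self.cout = in_channels, out_channels
        self.w = Param(name + ".w", _he_uniform(rng, (out_channels, in_channels), in_channels), True)

    def params(self) -> list[Param]:
        return [self.w]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x_flat = x.reshape(self.cin, -1) if training else None
        self._shape = x.shape
        out = self.w.value @ x.reshape(self.cin, -1)
        return out.reshape((self.cout,) + x.shape[1:])

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gm = grad.reshape(self.cout, -1)
        self.w.grad = gm @ self._x_flat.T
        dx = self.w.value.T @ gm
        self._x_flat = None
        return dx.reshape((self.cin,) + self._shape[1:])


class DepthwiseSeparableConv(Layer):
    """Depthwise stage followed by a 1x1 pointwise stage.

    Stage 1 convolves each input channel with its own kernel; stage 2 mixes
    channels with 1x1 kernels.  For ``c_in -> c_out`` channels and kernel of
    ``k`` taps this costs ``c_in*k + c_in*c_out`` weights versus
    ``c_in*k*c_out`` for a standard convolution.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: tuple[int, ...],
        rng: np.random.Generator,
        name: str = "dsconv",
    ) -> None:
        self.depthwise = DepthwiseConv(in_channels, kernel_size, rng, name + ".dw")
        self.pointwise = PointwiseConv(in_channels, out_channels, rng, name + ".pw")

    def params(self) -> list[Param]:
        return self.depthwise.params() + self.pointwise.params()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return self.pointwise.forward(self.depthwise.forward(x, training), training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.depthwise.backward(self.pointwise.backward(grad))


# ---------------------------------------------------------------------------
# normalization / activation / pooling / dense
# ---------------------------------------------------------------------------

class BatchNorm(Layer):
    """Per-channel batch normalization over batch and spatial axes.

    ``momentum`` follows the moving-average convention
    ``running = momentum * running + (1 - momentum) * batch_statistic``.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3,
                 name: str = "bn") -> None:
        self.momentum = float(momentum)
        self.eps = float(eps)
        self.gamma = Param(name + ".gamma", np.ones(channels, DTYPE), False)
        self.beta = Param(name + ".beta", np.zeros(channels, DTYPE), False)
        self.running_mean = np.zeros(channels, DTYPE)
        self.running_var = np.ones(channels, DTYPE)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def _bshape(self, ndim: int) -> tuple[int, ...]:
        return (-1,) + (1,) * (ndim - 1)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        C = x.shape[0]
        bs = self._bshape(x.ndim)
        xr = x.reshape(C, -1)
        m = xr.shape[1]
        if training:
            mean = xr.sum(axis=1) / m
            # single-pass variance: E[x^2] - E[x]^2 (adequate for BN inputs)
            var = np.einsum("ij,ij->i", xr, xr) / m - mean * mean
            np.maximum(var, 0.0, out=var)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(DTYPE)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(DTYPE)
            ivstd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean.astype(DTYPE).reshape(bs)) * ivstd.astype(DTYPE).reshape(bs)
            self._xhat, self._ivstd = xhat, ivstd.astype(DTYPE)
            return self.gamma.value.reshape(bs) * xhat + self.beta.value.reshape(bs)
        # eval: fused scale/shift from running statistics
        scale = (self.gamma.value / np.sqrt(self.running_var + self.eps)).astype(DTYPE)
        shift = (self.beta.value - scale * self.running_mean).astype(DTYPE)
        return x * scale.reshape(bs) + shift.reshape(bs)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        C = grad.shape[0]
        bs = self._bshape(grad.ndim)
        xhat, ivstd = self._xhat, self._ivstd
        gr = grad.reshape(C, -1)
        xr = xhat.reshape(C, -1)
        m = gr.shape[1]
        sum_g = gr.sum(axis=1)
        sum_gx = np.einsum("ij,ij->i", gr, xr)
        self.gamma.grad = sum_gx.astype(DTYPE)
        self.beta.grad = sum_g.astype(DTYPE)
        a = (self.gamma.value * ivstd).astype(DTYPE)
        b = (-a * sum_gx / m).astype(DTYPE)
        c = (-a * sum_g / m).astype(DTYPE)
        dx = grad * a.reshape(bs)
        dx += xhat * b.reshape(bs)
        dx += c.reshape(bs)
        self._xhat = self._ivstd = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad *= self._mask  # grad is layer-owned; safe to mutate
        self._mask = None
        return grad


class MaxPool(Layer):
    """Non-overlapping max pooling with window/stride 2 on every spatial axis.

    Odd trailing samples are dropped.  Ties go to the earlier element.
    """

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._in_shape = x.shape
        masks = []
        for ax in range(2, x.ndim):
            n = x.shape[ax] // 2
            sl0 = [slice(None)] * x.ndim
            sl1 = [slice(None)] * x.ndim
            sl0[ax] = slice(0, 2 * n, 2)
            sl1[ax] = slice(1, 2 * n, 2)
            a, b = x[tuple(sl0)], x[tuple(sl1)]
            take_a = a >= b
            x = np.where(take_a, a, b)
            if training:
                masks.append(take_a)
        if training:
            self._masks = masks
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        ndim = grad.ndim
        shape = self._in_shape
        for ax in reversed(range(2, ndim)):
            take_a = self._masks[ax - 2]
            n = grad.shape[ax]
            # rebuild this axis at its pre-pool length
            full = np.zeros(
                [shape[ax] if a == ax else s for a, s in enumerate(grad.shape)], DTYPE
            )
            sl0 = [slice(None)] * ndim
            sl1 = [slice(None)] * ndim
            sl0[ax] = slice(0, 2 * n, 2)
            sl1[ax] = slice(1, 2 * n, 2)
            full[tuple(sl0)] = grad * take_a
            full[tuple(sl1)] = grad * ~take_a
            grad = full
        self._masks = None
        return grad


class GlobalAvgPool(Layer):
    """Mean over all spatial axes; returns features as (B, C)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._in_shape = x.shape
        axes = tuple(range(2, x.ndim))
        return x.mean(axis=axes).T.astype(DTYPE)  # (B, C)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        shape = self._in_shape
        m = float(np.prod(shape[2:]))
        g = (grad.T / m).astype(DTYPE)  # (C, B)
        return np.broadcast_to(
            g.reshape(shape[:2] + (1,) * (len(shape) - 2)), shape
        ).copy()


class Dense(Layer):
    """Fully connected layer on (B, F) features, with bias."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 name: str = "dense") -> None:
        self.w = Param(name + ".w", _he_uniform(rng, (in_features, out_features), in_features), True)
        self.b = Param(name + ".b", np.zeros(out_features, DTYPE), False)

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad = self._x.T @ grad
        self.b.grad = grad.sum(axis=0)
        dx = grad @ self.w.value.T
        self._x = None
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray | None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
            if grad is None:
                return None
        return grad


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax of a (B, C) logit matrix."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
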