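"""Neural-network layers on top of the autodiff engine.

Convention: activations have shape (batch, time, channels). Layers are
callables taking ``(x, training=False, rng=None)``; stochastic layers
(dropout, input noise) draw from the supplied generator only when training.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, custom_op


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def params(self) -> list[Tensor]:
        return []

    def __call__(self, x: Tensor, training: bool = False, rng: np.random.Generator | None = None) -> Tensor:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, activation: str | None = None):
        self.w = Tensor(glorot_uniform(rng, (in_dim, out_dim), in_dim, out_dim), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)
        self.activation = activation

    def params(self):
        return [self.w, self.b]

    def __call__(self, x, training=False, rng=None):
        out = x @ self.w + self.b
        if self.activation == "relu":
            out = out.relu()
        elif self.activation == "sigmoid":
            out = out.sigmoid()
        elif self.activation == "tanh":
            out = out.tanh()
        return out


def _pad_time(x: np.ndarray, left: int, right: int) -> np.ndarray:
    if left == 0 and right == 0:
        return x
    return np.pad(x, ((0, 0), (left, right), (0, 0)))


class Conv1D(Layer):
    """Dilated 'same' 1-D convolution over the time axis."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator, dilation: int = 1):
        fan_in, fan_out = kernel * in_ch, kernel * out_ch
        self.w = Tensor(glorot_uniform(rng, (kernel, in_ch, out_ch), fan_in, fan_out), requires_grad=True)
        self.b = Tensor(np.zeros(out_ch), requires_grad=True)
        self.kernel = kernel
        self.dilation = dilation

    def params(self):
        return [self.w, self.b]

    def __call__(self, x, training=False, rng=None):
        w, b, d, K = self.w, self.b, self.dilation, self.kernel
        B, T, _ = x.shape
        span = d * (K - 1)
        left = span // 2
        xp = _pad_time(x.data, left, span - left)
        out = np.zeros((B, T, w.shape[2]))
        for k in range(K):
            out += xp[:, k * d : k * d + T, :] @ w.data[k]
        out += b.data

        def backward(g):
            if b.requires_grad:
                b._accumulate(g.sum(axis=(0, 1)))
            if w.requires_grad or x.requires_grad:
                dxp = np.zeros_like(xp) if x.requires_grad else None
                for k in range(K):
                    sl = xp[:, k * d : k * d + T, :]
                    if w.requires_grad:
                        w.grad = w.grad if w.grad is not None else np.zeros_like(w.data)
                        w.grad[k] += np.einsum("btc,bto->co", sl, g)
                    if dxp is not None:
                        dxp[:, k * d : k * d + T, :] += g @ w.data[k].T
                if dxp is not None:
                    x._accumulate(dxp[:, left : left + T, :])

        return custom_op(out, (x, w, b), backward)


class DepthwiseConv1D(Layer):
    """Per-channel 'same' convolution (the depthwise half of a separable conv)."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator, dilation: int = 1):
        self.w = Tensor(glorot_uniform(rng, (kernel, channels), kernel, kernel), requires_grad=True)
        self.kernel = kernel
        self.dilation = dilation

    def params(self):
        return [self.w]

    def __call__(self, x, training=False, rng=None):
        w, d, K = self.w, self.dilation, self.kernel
        B, T, C = x.shape
        span = d * (K - 1)
        left = span // 2
        xp = _pad_time(x.data, left, span - left)
        out = np.zeros((B, T, C))
        for k in range(K):
            out += xp[:, k * d : k * d + T, :] * w.data[k]

        def backward(g):
            dxp = np.zeros_like(xp) if x.requires_grad else None
            for k in range(K):
                if w.requires_grad:
                    w.grad = w.grad if w.grad is not None else np.zeros_like(w.data)
                    w.grad[k] += np.einsum("btc,btc->c", xp[:, k * d : k * d + T, :], g)
                if dxp is not None:
                    dxp[:, k * d : k * d + T, :] += g * w.data[k]
            if dxp is not None:
                x._accumulate(dxp[:, left : left + T, :])

        return custom_op(out, (x, w), backward)


class SeparableConv1D(Layer):
    """Depthwise convolution followed by a 1x1 pointwise convolution."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator, dilation: int = 1):
        self.depthwise = DepthwiseConv1D(in_ch, kernel, rng, dilation)
        self.pointwise = Conv1D(in_ch, out_ch, 1, rng)

    def params(self):
        return self.depthwise.params() + self.pointwise.params()

    def __call__(self, x, training=False, rng=None):
        return self.pointwise(self.depthwise(x))


class BatchNorm(Layer):
    """Batch normalization over (batch, time) per channel, with running stats."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def __call__(self, x, training=False, rng=None):
        if training:
            mu = x.mean(axis=(0, 1), keepdims=True)
            centered = x - mu
            var = (centered ** 2.0).mean(axis=(0, 1), keepdims=True)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mu.data.ravel()
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var.data.ravel()
            )
            xhat = centered * (var + self.eps) ** -0.5
        else:
            xhat = (x - self.running_mean) * (self.running_var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class LayerNorm(Layer):
    """Normalization over the last axis, per sample."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def __call__(self, x, training=False, rng=None):
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered ** 2.0).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5 * self.gamma + self.beta


class MaxPool1D(Layer):
    """Non-overlapping temporal max pooling by an integer factor."""

    def __init__(self, factor: int = 2):
        self.factor = factor

    def __call__(self, x, training=False, rng=None):
        B, T, C = x.shape
        f = self.factor
        Tp = T // f
        blocks = x.data[:, : Tp * f, :].reshape(B, Tp, f, C)
        arg = blocks.argmax(axis=2)
        out = np.take_along_axis(blocks, arg[:, :, None, :], axis=2)[:, :, 0, :]

        def backward(g):
            if x.requires_grad:
                dblocks = np.zeros_like(blocks)
                np.put_along_axis(dblocks, arg[:, :, None, :], g[:, :, None, :], axis=2)
                dx = np.zeros_like(x.data)
                dx[:, : Tp * f, :] = dblocks.reshape(B, Tp * f, C)
                x._accumulate(dx)

        return custom_op(out, (x,), backward)


class GlobalAveragePool(Layer):
    def __call__(self, x, training=False, rng=None):
        return x.mean(axis=1)


class SEBlock(Layer):
    """Squeeze-and-excitation: global temporal pooling + bottleneck gating.

    The sigmoid gate lies in (0, 1) per feature channel; bottleneck size is
    max(channels // 8, 8).
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        bottleneck = max(channels // 8, 8)
        self.fc1 = Dense(channels, bottleneck, rng, activation="relu")
        self.fc2 = Dense(bottleneck, channels, rng, activation="sigmoid")

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def gate(self, x: Tensor) -> Tensor:
        squeezed = x.mean(axis=1)  # (B, C)
        return self.fc2(self.fc1(squeezed))

    def __call__(self, x, training=False, rng=None):
        B, T, C = x.shape
        return x * self.gate(x).reshape(B, 1, C)


class AttentionPool(Layer):
    """Softmax-weighted temporal averaging; scores from a small tanh head.

    With an all-zero score head the weights are uniform and the layer
    reduces to global average pooling.
    """

    def __init__(self, channels: int, rng: np.random.Generator, hidden: int = 64):
        self.score1 = Dense(channels, hidden, rng, activation="tanh")
        self.score2 = Dense(hidden, 1, rng)

    def params(self):
        return self.score1.params() + self.score2.params()

    def weights(self, x: Tensor) -> Tensor:
        scores = self.score2(self.score1(x))  # (B, T, 1)
        return scores.softmax(axis=1)

    def __call__(self, x, training=False, rng=None):
        w = self.weights(x)
        return (x * w).sum(axis=1)


class Dropout(Layer):
    def __init__(self, rate: float):
        self.rate = rate

    def __call__(self, x, training=False, rng=None):
        if not training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep) / keep
        return x * mask


class SpatialDropout1D(Layer):
    """Drops whole feature channels (mask shared across time)."""

    def __init__(self, rate: float):
        self.rate = rate

    def __call__(self, x, training=False, rng=None):
        if not training or self.rate <= 0.0:
            return x
        B, _, C = x.shape
        keep = 1.0 - self.rate
        mask = (rng.random((B, 1, C)) < keep) / keep
        return x * mask


class GaussianNoise(Layer):
    def __init__(self, std: float):
        self.std = std

    def __call__(self, x, training=False, rng=None):
        if not training or self.std <= 0.0:
            return x
        return x + rng.normal(0.0, self.std, size=x.shape)
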