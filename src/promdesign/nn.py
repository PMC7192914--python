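"""Minimal neural-network engine for sequence-to-activity models.

Implements exactly the pieces the promoter model needs — 1-D convolution,
batch normalization, ReLU, max-pooling, dense layers, Huber loss and the
Adam optimizer — as numpy forward/backward passes.  Gradients can be
propagated all the way to the one-hot input, which is what the
gradient-ascent design strategy differentiates.

Shapes: convolutional stages use channels-last (batch, length, channels)
so that window slices feed matrix products without copies; dense stages
use (batch, features).  All computation is float32.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad", "l2")

    def __init__(self, value: np.ndarray, l2: bool = False):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)
        self.l2 = l2


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """1-D convolution, channels-last.

    ``y[:, j, :] = b + sum_t x[:, j + t, :] @ W[t]`` — one matrix product
    per kernel offset, avoiding an im2col copy.  With ``padding="same"``
    the input is zero-padded so the output length equals the input length
    (needed for deep stacks of conv + pool blocks); ``"valid"`` applies no
    padding.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        padding: str = "valid",
    ):
        if padding not in ("valid", "same"):
            raise ValueError("padding must be 'valid' or 'same'")
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        self.padding = padding
        self.W = Param(rng.normal(0.0, scale, (kernel, c_in, c_out)), l2=True)
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def _pad_widths(self):
        if self.padding == "valid":
            return 0, 0
        total = self.kernel - 1
        return total // 2, total - total // 2

    def forward(self, x, train):
        k = self.kernel
        p5, p3 = self._pad_widths()
        if p5 or p3:
            x = np.pad(x, ((0, 0), (p5, p3), (0, 0)))
        B, P, C = x.shape
        Lp = P - k + 1
        self._x = x
        x2 = x.reshape(-1, C)
        y = np.tile(self.b.value, (B, Lp, 1))
        for t in range(k):
            # one large GEMM per offset, then a shifted accumulate
            z = (x2 @ self.W.value[t]).reshape(B, P, self.c_out)
            y += z[:, t : t + Lp, :]
        return y

    def backward(self, dout):
        x = self._x
        k = self.kernel
        B, P, C = x.shape
        Lp = dout.shape[1]
        W = self.W.value
        dx = np.zeros_like(x)
        d2 = dout.reshape(-1, self.c_out)
        g = (d2 @ W.reshape(-1, self.c_out).T).reshape(B, Lp, k, C)
        for t in range(k):
            xs = np.ascontiguousarray(x[:, t : t + Lp, :]).reshape(-1, C)
            self.W.grad[t] += xs.T @ d2
            dx[:, t : t + Lp, :] += g[:, :, t, :]
        self.b.grad += d2.sum(axis=0)
        p5, p3 = self._pad_widths()
        if p5 or p3:
            dx = dx[:, p5 : P - p3, :]
        return dx


class BatchNorm(Layer):
    """Batch normalization over batch (and length, for conv stages),
    applied before the nonlinearity.  Running statistics are used at
    inference time."""

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_channels))
        self.beta = Param(np.zeros(n_channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_channels, dtype=DTYPE)
        self.running_var = np.ones(n_channels, dtype=DTYPE)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        axes = (0, 1) if x.ndim == 3 else (0,)
        if train:
            x2 = x.reshape(-1, x.shape[-1])  # contiguous flatten: fast reduction
            mean = x2.mean(axis=0)
            var = x2.var(axis=0)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(DTYPE)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, axes, train)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout):
        xhat, inv_std, axes, train = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value
        if not train:
            return dxhat * inv_std
        n = np.prod([xhat.shape[a] for a in axes])
        s1 = dxhat.sum(axis=axes, keepdims=True)
        s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
        return (inv_std / n) * (n * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool1d(Layer):
    """Max-pooling along the length axis (window = stride by default)."""

    def __init__(self, stride: int = 2, width: int | None = None):
        self.stride = stride
        self.width = width or stride

    def forward(self, x, train):
        w, s = self.width, self.stride
        self._in_shape = x.shape
        if w == 2 and s == 2:
            Lp = (x.shape[1] - 2) // 2 + 1
            a = x[:, 0 : 2 * Lp : 2, :]
            b = x[:, 1 : 2 * Lp : 2, :]
            take_b = b > a
            self._pos = 2 * np.arange(Lp)[None, :, None] + take_b
            return np.where(take_b, b, a)
        win = np.lib.stride_tricks.sliding_window_view(x, w, axis=1)[:, ::s]
        idx = win.argmax(axis=3)  # (B, L', C)
        self._pos = idx + s * np.arange(idx.shape[1])[None, :, None]
        return np.take_along_axis(x, self._pos, axis=1)

    def backward(self, dout):
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        B, Lp, C = self._pos.shape
        bi, _, ci = np.indices((B, Lp, C), sparse=True)
        if self.width <= self.stride:
            # non-overlapping windows: no collisions, plain scatter
            dx[bi, self._pos, ci] = dout
        else:
            np.add.at(dx, (bi, self._pos, ci), dout)
        return dx


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(
        self,
        f_in: int,
        f_out: int,
        rng: np.random.Generator,
        l2: bool = True,
        init_scale: float | None = None,
    ):
        scale = np.sqrt(2.0 / f_in) if init_scale is None else init_scale
        self.W = Param(rng.normal(0.0, scale, (f_in, f_out)), l2=l2)
        self.b = Param(np.zeros(f_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = np.asarray(dout, dtype=DTYPE)
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def set_weights(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        for p, v in zip(ps, state[: len(ps)]):
            p.value[...] = v
        rest = state[len(ps) :]
        i = 0
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = rest[i]
                layer.running_var[...] = rest[i + 1]
                i += 2

    def input_gradient(self, x: np.ndarray, out_weights: np.ndarray) -> np.ndarray:
        """d(sum_j out_weights[j] * y[:, j]) / dx at inference statistics."""
        y = self.forward(x, train=False)
        dout = np.broadcast_to(np.asarray(out_weights, dtype=DTYPE), y.shape)
        return self.backward(dout.copy())


def huber(
    y: np.ndarray, y_hat: np.ndarray, delta: float = 0.15
) -> tuple[float, np.ndarray]:
    """Mean Huber loss and its gradient with respect to ``y_hat``.

    Quadratic within ``delta`` of the target, linear beyond; multiple
    outputs are weighted equally (the mean runs over every element).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    e = np.asarray(y_hat, dtype=float) - np.asarray(y, dtype=float)
    small = np.abs(e) <= delta
    loss = np.where(small, 0.5 * e**2, delta * (np.abs(e) - delta / 2.0))
    grad = np.where(small, e, delta * np.sign(e)) / e.size
    return float(loss.mean()), grad


class Adam:
    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-5,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        l2_weight: float = 0.0,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.l2_weight = l2_weight
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            if p.l2 and self.l2_weight:
                g = g + 2.0 * self.l2_weight * p.value
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def l2_penalty(self) -> float:
        if not self.l2_weight:
            return 0.0
        return self.l2_weight * sum(
            float((p.value**2).sum()) for p in self.params if p.l2
        )
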