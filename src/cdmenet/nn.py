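"""Minimal CPU neural-network primitives with hand-written backpropagation.

Layers operate on single images shaped (C, H, W) in float64, matching the
batch-size-1 training protocol.  Every layer caches what its backward pass
needs during ``forward`` and accumulates parameter gradients in ``backward``.
Convolutions are expressed as a sum over kernel taps of shifted views, which
keeps dilation support trivial and is fast enough at desk scale.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Layer", "Conv2d", "ReLU", "Sigmoid", "MaxPool2x2", "Sequential", "Adam"]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """2-D convolution with 'same'-style zero padding and optional dilation.

    Weight shape (out_ch, in_ch, k, k); He-normal initialisation from the
    supplied generator so builds are seed-reproducible.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        rng: np.random.Generator,
        dilation: int = 1,
        padding: int | None = None,
    ):
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.dilation = dilation
        self.padding = dilation * (kernel // 2) if padding is None else padding
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Param(rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)))
        self.bias = Param(np.zeros(out_ch))
        self._x_padded: np.ndarray | None = None

    def parameters(self) -> list[Param]:
        return [self.weight, self.bias]

    def _tap_slices(self, h: int, w: int):
        k, d = self.kernel, self.dilation
        for i in range(k):
            for j in range(k):
                yield i, j, slice(i * d, i * d + h), slice(j * d, j * d + w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 3 or x.shape[0] != self.in_ch:
            raise ValueError(
                f"expected ({self.in_ch}, H, W) input, got {x.shape}"
            )
        p = self.padding
        xp = np.pad(x, ((0, 0), (p, p), (p, p)))
        h = xp.shape[1] - self.dilation * (self.kernel - 1)
        w = xp.shape[2] - self.dilation * (self.kernel - 1)
        self._x_padded = xp
        wm = self.weight.value.reshape(self.out_ch, self.in_ch, -1)
        out = np.zeros((self.out_ch, h, w))
        for i, j, si, sj in self._tap_slices(h, w):
            # (out, in) @ (in, h*w) accumulated per kernel tap
            out += np.tensordot(self.weight.value[:, :, i, j], xp[:, si, sj], axes=1)
        out += self.bias.value[:, None, None]
        del wm
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xp = self._x_padded
        assert xp is not None, "backward before forward"
        h, w = gout.shape[1:]
        gxp = np.zeros_like(xp)
        for i, j, si, sj in self._tap_slices(h, w):
            patch = xp[:, si, sj]
            self.weight.grad[:, :, i, j] += np.tensordot(
                gout.reshape(self.out_ch, -1), patch.reshape(self.in_ch, -1).T, axes=1
            )
            gxp[:, si, sj] += np.tensordot(
                self.weight.value[:, :, i, j].T, gout, axes=1
            )
        self.bias.grad += gout.sum(axis=(1, 2))
        p = self.padding
        if p:
            return gxp[:, p:-p, p:-p]
        return gxp


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gout, 0.0)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._out * (1.0 - self._out)


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/cols are rejected."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"pooling needs even spatial dims, got {(h, w)}")
        xb = x.reshape(c, h // 2, 2, w // 2, 2)
        flat = xb.transpose(0, 1, 3, 2, 4).reshape(c, h // 2, w // 2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        c, h, w = self._in_shape
        flat = np.zeros((c, h // 2, w // 2, 4))
        np.put_along_axis(flat, self._argmax[..., None], gout[..., None], axis=-1)
        return (
            flat.reshape(c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 3, 2, 4)
            .reshape(c, h, w)
        )


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def parameters(self) -> list[Param]:
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            gout = l.backward(gout)
        return gout


class Adam:
    """Adaptive-moment optimiser with the usual library defaults."""

    def __init__(self, params: list[Param], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
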