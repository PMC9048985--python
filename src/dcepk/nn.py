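"""Minimal NumPy building blocks for the dual-pathway convolutional network.

Layers operate on NHWC float32 tensors and implement explicit forward and
backward passes.  2-D convolution gathers the k*k kernel taps into one
im2col matrix so the whole operation is a single
(N*H*W, k*k*Cin) x (k*k*Cin, Cout) BLAS call; the backward pass reuses
the cached column matrix for the weight gradient and scatter-adds the
input gradient tap by tap.  Zero padding is size-preserving for any
dilation; with an even kernel the extra pad column/row goes after, so
output H, W always equal input H, W.

Everything is deterministic given the seed of the generator used for
initialization and batch shuffling.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "DepthwiseConv2D", "ReLU", "Adam"]


def _same_pad(k: int, dilation: int):
    span = (k - 1) * dilation
    before = span // 2
    return before, span - before


class Layer:
    """Base layer: ``params()`` yields (name, value, grad) triples."""

    def params(self):
        return []

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """Zero-padded, size-preserving 2-D convolution (optionally dilated).

    Kernel 1x1 degenerates to a per-pixel fully connected layer, which is
    exactly how the network head realizes its "fully connected" stack.
    """

    def __init__(self, cin: int, cout: int, k: int = 4, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.dilation = k, dilation
        self.cin, self.cout = cin, cout
        std = np.sqrt(2.0 / (k * k * cin))
        self.w = rng.normal(0.0, std, (k, k, cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]

    def _im2col(self, xp, h, w):
        """Gather kernel taps into one (N*H*W, k*k*Cin) matrix."""
        n = xp.shape[0]
        d = self.dilation
        cols = np.empty((n * h * w, self.k * self.k * self.cin), dtype=np.float32)
        t = 0
        for i in range(self.k):
            for j in range(self.k):
                patch = xp[:, i * d:i * d + h, j * d:j * d + w, :]
                cols[:, t * self.cin:(t + 1) * self.cin] = patch.reshape(-1, self.cin)
                t += 1
        return cols

    def forward(self, x, train=True):
        if x.shape[-1] != self.cin:
            raise ValueError(f"expected {self.cin} channels, got {x.shape[-1]}")
        n, h, w, _ = x.shape
        if self.k == 1:
            if train:
                self._x = x
            out = x.reshape(-1, self.cin) @ self.w[0, 0] + self.b
            return out.reshape(n, h, w, self.cout)
        pb, pa = _same_pad(self.k, self.dilation)
        xp = np.pad(x, ((0, 0), (pb, pa), (pb, pa), (0, 0)))
        cols = self._im2col(xp, h, w)
        if train:
            self._cols, self._xshape = cols, x.shape
        out = cols @ self.w.reshape(-1, self.cout) + self.b
        return out.reshape(n, h, w, self.cout)

    def backward(self, grad):
        grad = grad.astype(np.float32, copy=False)
        self.db[...] = grad.sum(axis=(0, 1, 2))
        g2 = grad.reshape(-1, self.cout)
        if self.k == 1:
            x = self._x
            self.dw[0, 0] = x.reshape(-1, self.cin).T @ g2
            return (g2 @ self.w[0, 0].T).reshape(x.shape)
        n, h, w, _ = self._xshape
        cols = self._cols
        self.dw[...] = (cols.T @ g2).reshape(self.w.shape)
        dcols = g2 @ self.w.reshape(-1, self.cout).T
        pb, pa = _same_pad(self.k, self.dilation)
        d = self.dilation
        dxp = np.zeros((n, h + pb + pa, w + pb + pa, self.cin), dtype=np.float32)
        t = 0
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i * d:i * d + h, j * d:j * d + w, :] += \
                    dcols[:, t * self.cin:(t + 1) * self.cin].reshape(n, h, w, self.cin)
                t += 1
        return dxp[:, pb:pb + h, pb:pb + w, :]


class DepthwiseConv2D(Layer):
    """Size-preserving depthwise convolution: one k x k filter per channel."""

    def __init__(self, channels: int, k: int = 4,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.c = k, channels
        std = np.sqrt(2.0 / (k * k))
        self.w = rng.normal(0.0, std, (k, k, channels)).astype(np.float32)
        self.b = np.zeros(channels, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]

    def forward(self, x, train=True):
        if x.shape[-1] != self.c:
            raise ValueError(f"expected {self.c} channels, got {x.shape[-1]}")
        pb, pa = _same_pad(self.k, 1)
        xp = np.pad(x, ((0, 0), (pb, pa), (pb, pa), (0, 0)))
        if train:
            self._xp = xp
        n, h, w, _ = x.shape
        out = np.broadcast_to(self.b, (n, h, w, self.c)).copy()
        for i in range(self.k):
            for j in range(self.k):
                out += xp[:, i:i + h, j:j + w, :] * self.w[i, j]
        return out

    def backward(self, grad):
        grad = grad.astype(np.float32, copy=False)
        self.db[...] = grad.sum(axis=(0, 1, 2))
        xp = self._xp
        pb, pa = _same_pad(self.k, 1)
        n, hp, wp, _ = xp.shape
        h, w = hp - pb - pa, wp - pb - pa
        dxp = np.zeros_like(xp)
        for i in range(self.k):
            for j in range(self.k):
                patch = xp[:, i:i + h, j:j + w, :]
                self.dw[i, j] = (patch * grad).sum(axis=(0, 1, 2))
                dxp[:, i:i + h, j:j + w, :] += grad * self.w[i, j]
        return dxp[:, pb:pb + h, pb:pb + w, :]


class ReLU(Layer):
    def forward(self, x, train=True):
        out = np.maximum(x, 0.0)
        if train:
            self._pos = x > 0
        return out

    def backward(self, grad):
        return grad * self._pos


class Adam:
    """Adam optimizer with (coupled) L2 weight penalty.

    The penalty lambda/2 * ||w||^2 is added to the loss for weights (not
    biases); its gradient lambda * w joins the data gradient before the
    moment updates.
    """

    def __init__(self, params, lr: float = 1e-4, l2: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)  # (name, value, grad) triples
        self.lr, self.l2 = lr, l2
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(v) for _, v, _ in self.params]
        self.v = [np.zeros_like(v) for _, v, _ in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (name, value, grad) in enumerate(self.params):
            g = grad
            if self.l2 > 0 and name == "w":
                g = g + self.l2 * value
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(value.dtype)
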