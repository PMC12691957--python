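"""Minimal CPU neural-net layer stack: im2col convolutions, manual backward, Adam.

Both networks in this package (the anchor-based proposal detector and the
Siamese similarity filter) are small convolutional models trained on
synthetic phantoms, so a compact float32 numpy implementation with explicit
forward/backward passes is sufficient and keeps the package dependency-free
beyond the scientific stack.  Layers cache what their backward pass needs;
``backward`` returns the gradient w.r.t. the layer input and accumulates
parameter gradients in-place.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(parameter, gradient-accumulator) pairs."""
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (e.g. batch-norm running statistics)."""
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution with zero padding k//2, arbitrary stride."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        fan_in = c_in * k * k
        self.w = (rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (xp.shape[2] - k) // s + 1
        wo = (xp.shape[3] - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (n, c, ho, wo, k, k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * k * k
        )
        y = cols @ self.w.T + self.b
        if train:
            self._cols = cols
            self._xshape = (n, c, h, w, ho, wo, xp.shape[2], xp.shape[3])
        return y.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w, ho, wo, hp, wp = self._xshape
        k, s, p = self.k, self.stride, self.k // 2
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(n * ho * wo, self.c_out)
        self.dw += dyf.T @ self._cols
        self.db += dyf.sum(axis=0)
        dcols = (dyf @ self.w).reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros((n, c, hp, wp), dtype=F32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, i, j]
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for eval mode."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(c, dtype=F32)
        self.run_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def buffers(self):
        return [self.run_mean, self.run_var]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean += self.momentum * (mean - self.run_mean)
            self.run_var += self.momentum * (var - self.run_var)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
            self._xhat, self._inv = xhat, inv
        else:
            inv = 1.0 / np.sqrt(self.run_var + self.eps)
            xhat = (x - self.run_mean[None, :, None, None]) * inv[None, :, None, None]
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.dgamma += (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta += dy.sum(axis=(0, 2, 3))
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * self.gamma[None, :, None, None]
        t1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        t2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (dxhat - t1 / m - xhat * t2 / m) * inv[None, :, None, None]
        self._xhat = None
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Tanh(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.tanh(x)
        if train:
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * (1.0 - self._y**2)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def buffers(self):
        return [b for l in self.layers for b in l.buffers()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Residual(Layer):
    """Pre-activation residual block: y = x + body(relu-in-body(x)); shapes must match."""

    def __init__(self, body: Layer):
        self.body = body

    def params(self):
        return self.body.params()

    def buffers(self):
        return self.body.buffers()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x + self.body.forward(x, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy + self.body.backward(dy)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), self._shape).astype(F32).copy()


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((d_out, d_in)) * np.sqrt(1.0 / d_in)).astype(F32)
        self.b = np.zeros(d_out, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw += dy.T @ self._x
        self.db += dy.sum(axis=0)
        return dy @ self.w


class Adam:
    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Numerically stable BCE; returns (mean loss, d loss / d logits)."""
    p = sigmoid(logits)
    loss = np.maximum(logits, 0) - logits * targets + np.log1p(np.exp(-np.abs(logits)))
    n = max(logits.size, 1)
    return float(loss.mean()) if logits.size else 0.0, (p - targets) / n


def state_dict(layer: Layer) -> list[np.ndarray]:
    return [p.copy() for p, _ in layer.params()] + [b.copy() for b in layer.buffers()]


def load_state(layer: Layer, state: list[np.ndarray]) -> None:
    own = [p for p, _ in layer.params()] + layer.buffers()
    if len(own) != len(state):
        raise ValueError("state does not match model")
    for p, s in zip(own, state):
        if p.shape != s.shape:
            raise ValueError(f"shape mismatch {p.shape} vs {s.shape}")
        p[...] = s.astype(F32)
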