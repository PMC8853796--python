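"""Minimal NumPy neural-network layers with hand-written backpropagation.

Everything the encoder-decoder segmentation network needs — 2-D "same"
convolution, batch normalisation, ReLU, 2x2 max pooling, 2x nearest
upsampling, channel concatenation, softmax cross-entropy and Adam — is
implemented here directly on NHWC float arrays.  Convolutions are computed
as a sum over the k*k kernel positions of (pixels x channels) matrix
products, which keeps memory flat and hands the heavy lifting to BLAS.

Layers expose ``forward(x, train)`` and ``backward(dy)``; in training mode
forward caches what backward needs, in eval mode nothing is cached so
whole-image inference on multi-megapixel inputs stays memory-bounded.
Parameters and their gradient buffers are exposed through ``params()`` for
the optimiser.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """(name, value, gradient-accumulator) triples; empty by default."""
        return []

    def zero_grad(self) -> None:
        for _, _, g in self.params():
            g[...] = 0.0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """k x k convolution with 'same' zero padding, stride 1, He init.

    Forward lowers the input to an im2col matrix of shape
    (N*H*W, k*k*cin) and performs a single GEMM against the flattened
    kernel; backward reuses the cached column matrix for the weight
    gradient and folds the column-space gradient back with k*k
    shifted adds.
    """

    def __init__(self, cin: int, cout: int, ksize: int,
                 rng: np.random.Generator, dtype=np.float32,
                 name: str = "conv"):
        fan_in = ksize * ksize * cin
        self.W = (rng.standard_normal((ksize, ksize, cin, cout))
                  * np.sqrt(2.0 / fan_in)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.ksize = ksize
        self.name = name
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self):
        return [(f"{self.name}.W", self.W, self.dW),
                (f"{self.name}.b", self.b, self.db)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, pad = self.ksize, self.ksize // 2
        n, h, w, c = x.shape
        if k == 1:
            return x.reshape(-1, c)
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        windows = np.lib.stride_tricks.sliding_window_view(
            xp, (k, k), axis=(1, 2))  # (n, h, w, c, k, k)
        cols = windows.transpose(0, 1, 2, 4, 5, 3).reshape(
            n * h * w, k * k * c)
        return np.ascontiguousarray(cols)

    def forward(self, x, train):
        n, h, w, c = x.shape
        k, pad = self.ksize, self.ksize // 2
        cout = self.W.shape[3]
        if train:
            # im2col + one large GEMM; the column matrix is cached for the
            # weight gradient, so the memory is spent only while training
            cols = self._im2col(x)
            y = cols @ self.W.reshape(-1, cout)
            y += self.b
            self._cols = cols
            self._xshape = x.shape
            return y.reshape(n, h, w, cout)
        # eval mode: accumulate the k*k shifted products without ever
        # materialising columns, keeping whole-image inference memory-flat
        if k == 1:
            y = x @ self.W[0, 0]
            y += self.b
            return y
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        y = np.empty((n, h, w, cout), dtype=x.dtype)
        y[...] = self.b
        for di in range(k):
            for dj in range(k):
                y += xp[:, di:di + h, dj:dj + w, :] @ self.W[di, dj]
        return y

    def backward(self, dy):
        cols = self._cols
        assert cols is not None, "backward before training-mode forward"
        self._cols = None
        k, pad = self.ksize, self.ksize // 2
        n, h, w, c = self._xshape
        cout = self.W.shape[3]
        dy2 = dy.reshape(-1, cout)
        self.db += dy2.sum(axis=0)
        self.dW += (cols.T @ dy2).reshape(self.W.shape)
        wm = self.W.reshape(-1, cout)
        dcols = dy2 @ wm.T  # (n*h*w, k*k*c)
        if k == 1:
            return dcols.reshape(n, h, w, c)
        dcols = dcols.reshape(n, h, w, k, k, c)
        dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=dy.dtype)
        for di in range(k):
            for dj in range(k):
                dxp[:, di:di + h, dj:dj + w, :] += dcols[:, :, :, di, dj, :]
        return dxp[:, pad:pad + h, pad:pad + w, :]


class BatchNorm(Layer):
    """Per-channel batch normalisation over the (N, H, W) axes."""

    def __init__(self, c: int, dtype=np.float32, momentum: float = 0.9,
                 eps: float = 1e-5, name: str = "bn"):
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self.name = name
        self._cache = None

    def params(self):
        return [(f"{self.name}.gamma", self.gamma, self.dgamma),
                (f"{self.name}.beta", self.beta, self.dbeta)]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean[...] = (self.momentum * self.running_mean
                                      + (1 - self.momentum) * mean)
            self.running_var[...] = (self.momentum * self.running_var
                                     + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv.astype(x.dtype))
        return self.gamma * xhat + self.beta

    def backward(self, dy):
        xhat, inv = self._cache
        self._cache = None
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        dg = (dy * xhat).sum(axis=(0, 1, 2))
        db = dy.sum(axis=(0, 1, 2))
        self.dgamma += dg
        self.dbeta += db
        return (self.gamma * inv / m) * (m * dy - db - xhat * dg)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train):
        y = np.maximum(x, 0)
        self._mask = x > 0 if train else None
        return y

    def backward(self, dy):
        mask = self._mask
        self._mask = None
        return dy * mask


class MaxPool2(Layer):
    """2x2 max pooling; ties resolve to the first (row-major) maximum."""

    def __init__(self):
        self._cache = None

    def forward(self, x, train):
        n, h, w, c = x.shape
        assert h % 2 == 0 and w % 2 == 0, "pool input must have even sides"
        xr = (x.reshape(n, h // 2, 2, w // 2, 2, c)
              .transpose(0, 1, 3, 5, 2, 4)
              .reshape(n, h // 2, w // 2, c, 4))
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape) if train else None
        return y

    def backward(self, dy):
        idx, (n, h, w, c) = self._cache
        self._cache = None
        flat = np.zeros((n, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(flat, idx[..., None], dy[..., None], axis=-1)
        return (flat.reshape(n, h // 2, w // 2, c, 2, 2)
                .transpose(0, 1, 4, 2, 5, 3)
                .reshape(n, h, w, c))


class Upsample2(Layer):
    """Parameter-free 2x nearest-neighbour enlargement."""

    def forward(self, x, train):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy):
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                          class_weights: np.ndarray | None = None,
                          ) -> tuple[float, np.ndarray]:
    """Mean per-pixel cross-entropy and its gradient w.r.t. the logits.

    ``logits`` is (N, H, W, C), ``labels`` (N, H, W) integer classes.
    Optional per-class weights rescale each pixel's contribution.
    """
    z = logits - logits.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logsumexp
    n_px = labels.size
    picked = np.take_along_axis(logp, labels[..., None].astype(np.int64),
                                axis=-1)[..., 0]
    if class_weights is None:
        loss = -picked.sum() / n_px
        grad = np.exp(logp)
        np.subtract.at(grad.reshape(-1, grad.shape[-1]),
                       (np.arange(n_px), labels.reshape(-1)), 1.0)
        grad /= n_px
    else:
        wpix = class_weights[labels]
        wsum = wpix.sum()
        loss = -(picked * wpix).sum() / wsum
        grad = np.exp(logp) * wpix[..., None]
        np.subtract.at(grad.reshape(-1, grad.shape[-1]),
                       (np.arange(n_px), labels.reshape(-1)),
                       wpix.reshape(-1))
        grad /= wsum
    return float(loss), grad.astype(logits.dtype)


class Adam:
    """Adam optimiser over a network's (value, grad) parameter pairs."""

    def __init__(self, net: Layer, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.state = {name: (np.zeros_like(v), np.zeros_like(v))
                      for name, v, _ in net.params()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for name, v, g in self.net.params():
            m, s = self.state[name]
            m[...] = b1 * m + (1 - b1) * g
            s[...] = b2 * s + (1 - b2) * g * g
            v -= (self.lr * (m / bias1)
                  / (np.sqrt(s / bias2) + self.eps)).astype(v.dtype)
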