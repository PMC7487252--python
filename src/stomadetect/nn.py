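"""Minimal seeded NumPy backend for training and scoring the patch CNNs.

Implements exactly the layer vocabulary of :mod:`.architectures`
(3x3 convolutions with valid or same padding, 2x2 max pooling, dense
layers, inverted dropout, 2-way softmax output) with ReLU activations,
softmax cross-entropy loss and the Adam optimizer.  All arithmetic is
float32 and BLAS-backed (convolutions are evaluated as nine shifted
matrix products), which is fast enough for desk-scale training of the
basic architectures on a single CPU.

Everything is driven by explicit ``numpy.random.Generator`` streams, so a
fixed seed reproduces initialization, batch order, dropout masks and
hence the whole loss history bit-for-bit on a given platform.
"""

from __future__ import annotations

import numpy as np

from .architectures import ArchitectureSpec, resolve_shapes

__all__ = ["SequentialNet", "Adam", "softmax_cross_entropy"]


def _relu(x):
    return np.maximum(x, 0.0)


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean negative log-likelihood of integer labels under ``probs``."""
    n = len(y)
    return float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())


class _Layer:
    params: tuple = ()
    grads: tuple = ()
    trainable = True

    def forward(self, x, train, rng):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, H, W, C) → (N·(H−2)·(W−2), 9·C) patch matrix for a 3x3 window."""
    N, H, W, C = x.shape
    v = np.lib.stride_tricks.sliding_window_view(x, (3, 3), axis=(1, 2))
    # (N, Ho, Wo, C, 3, 3) → (N, Ho, Wo, 3, 3, C) so columns order as (dy, dx, c)
    v = v.transpose(0, 1, 2, 4, 5, 3)
    return np.ascontiguousarray(v).reshape(N * (H - 2) * (W - 2), 9 * C)


class _Conv3x3(_Layer):
    def __init__(self, c_in, c_out, same, rng):
        # He initialization for ReLU units
        fan_in = 9 * c_in
        self.W = (rng.standard_normal((3, 3, c_in, c_out)) *
                  np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.same = same
        self.params = (self.W, self.b)

    def forward(self, x, train, rng):
        if self.same:
            x = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        N, H, W, _ = x.shape
        Ho, Wo = H - 2, W - 2
        c_out = len(self.b)
        col = _im2col(x)
        out = (col @ self.W.reshape(-1, c_out) + self.b).reshape(N, Ho, Wo, c_out)
        self._col, self._in_shape = col, x.shape
        self._pre = out
        return _relu(out)

    def backward(self, dout, need_dx=True):
        dout = dout * (self._pre > 0)
        N, H, W, C = self._in_shape
        Ho, Wo = H - 2, W - 2
        c_out = len(self.b)
        dflat = dout.reshape(-1, c_out)
        dW = (self._col.T @ dflat).reshape(self.W.shape)
        db = dflat.sum(axis=0)
        self.grads = (dW, db)
        dx = None
        if need_dx:
            dcol = (dflat @ self.W.reshape(-1, c_out).T).reshape(N, Ho, Wo, 3, 3, C)
            dx = np.zeros(self._in_shape, dtype=dout.dtype)
            for dy in range(3):
                for dx_ in range(3):
                    dx[:, dy:dy + Ho, dx_:dx_ + Wo, :] += dcol[:, :, :, dy, dx_, :]
            if self.same:
                dx = dx[:, 1:-1, 1:-1, :]
        self._col = self._pre = None
        return dx


class _MaxPool2x2(_Layer):
    def forward(self, x, train, rng):
        N, H, W, C = x.shape
        H2, W2 = H // 2, W // 2
        self._in_shape = x.shape
        xr = (x[:, :2 * H2, :2 * W2, :]
              .reshape(N, H2, 2, W2, 2, C)
              .transpose(0, 1, 3, 5, 2, 4)
              .reshape(N, H2, W2, C, 4))
        self._idx = xr.argmax(axis=4)
        return np.take_along_axis(xr, self._idx[..., None], axis=4)[..., 0]

    def backward(self, dout):
        N, H, W, C = self._in_shape
        H2, W2 = H // 2, W // 2
        dxr = np.zeros((N, H2, W2, C, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=4)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, :2 * H2, :2 * W2, :] = (dxr
                                      .reshape(N, H2, W2, C, 2, 2)
                                      .transpose(0, 1, 4, 2, 5, 3)
                                      .reshape(N, 2 * H2, 2 * W2, C))
        self._idx = None
        return dx


class _Flatten(_Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(len(x), -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class _Dense(_Layer):
    def __init__(self, n_in, n_out, rng, output=False):
        scale = np.sqrt(1.0 / n_in) if output else np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.output = output
        self.params = (self.W, self.b)

    def forward(self, x, train, rng):
        self._x = x
        z = x @ self.W + self.b
        if self.output:
            return _softmax(z)
        self._pre = z
        return _relu(z)

    def backward(self, dout):
        # for the output layer, dout is already d(loss)/d(logits)
        if not self.output:
            dout = dout * (self._pre > 0)
        self.grads = (self._x.T @ dout, dout.sum(axis=0))
        dx = dout @ self.W.T
        self._x = self._pre = None
        return dx


class _Dropout(_Layer):
    def __init__(self, rate):
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class SequentialNet:
    """A feed-forward net instantiated from an :class:`ArchitectureSpec`."""

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator,
                 dropout_rate: float = 0.5):
        shapes = [spec.input_shape] + resolve_shapes(spec)
        self.spec = spec
        self.layers: list[_Layer] = []
        for i, ls in enumerate(spec.layers):
            in_shape = shapes[i]
            if ls.kind in ("conv3x3_valid", "conv3x3_same"):
                layer = _Conv3x3(in_shape[2], ls.channels_or_units,
                                 ls.kind == "conv3x3_same", rng)
            elif ls.kind == "maxpool2x2":
                layer = _MaxPool2x2()
            elif ls.kind == "flatten":
                layer = _Flatten()
            elif ls.kind == "dense":
                layer = _Dense(in_shape[0], ls.channels_or_units, rng)
            elif ls.kind == "softmax_output":
                layer = _Dense(in_shape[0], ls.channels_or_units, rng, output=True)
            elif ls.kind == "dropout":
                layer = _Dropout(dropout_rate)
            else:  # pragma: no cover
                raise ValueError(ls.kind)
            layer.trainable = i >= spec.frozen_prefix
            self.layers.append(layer)
        self._first_trainable = spec.frozen_prefix

    def num_params(self) -> int:
        return sum(int(p.size) for l in self.layers for p in l.params)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate from d(loss)/d(logits); stops at the frozen base.

        The input gradient of the lowest layer reached is never consumed,
        so convolutions there skip computing it.
        """
        d = dlogits
        for i in range(len(self.layers) - 1, self._first_trainable - 1, -1):
            layer = self.layers[i]
            if i == self._first_trainable and isinstance(layer, _Conv3x3):
                layer.backward(d, need_dx=False)
            else:
                d = layer.backward(d)

    def trainable_params(self):
        for layer in self.layers:
            if layer.trainable and layer.params:
                yield layer

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for l in self.layers for p in l.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        i = 0
        for l in self.layers:
            if not l.params:
                continue
            W, b = weights[i], weights[i + 1]
            l.W[...] = W
            l.b[...] = b
            i += 2
        if i != len(weights):
            raise ValueError("weight list does not match the architecture")


class Adam:
    """Adam with bias correction, applied to the trainable layers only."""

    def __init__(self, net: SequentialNet, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = {id(l): [np.zeros_like(p) for p in l.params]
                   for l in net.trainable_params()}
        self._v = {id(l): [np.zeros_like(p) for p in l.params]
                   for l in net.trainable_params()}

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for layer in self.net.trainable_params():
            m, v = self._m[id(layer)], self._v[id(layer)]
            for p, g, mi, vi in zip(layer.params, layer.grads, m, v):
                mi *= self.b1
                mi += (1 - self.b1) * g
                vi *= self.b2
                vi += (1 - self.b2) * g * g
                p -= self.lr * (mi / bc1) / (np.sqrt(vi / bc2) + self.eps)
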