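"""Minimal CPU neural-network engine (float32, numpy) for the GAF classifier.

Implements exactly the pieces the identification network needs: 3x3 same-pad
convolutions, ReLU, 2x2 max pooling, global average pooling, inverted
dropout, dense layers, softmax cross-entropy and Adam.  Activations use
channels-last layout ``(batch, height, width, channels)`` so convolutions
reduce to nine BLAS matmuls over contiguous slices.  Everything is
deterministic given the training Generator; no other framework is involved.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "GlobalAvgPool",
    "Dropout",
    "Flatten",
    "Dense",
    "Network",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


class Layer:
    """Forward/backward interface; parameterised layers expose params/grads."""

    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 convolution, stride 1, same padding, He-initialised.

    The kernel is stored as 9 offset matrices ``W[o]`` of shape
    ``(c_in, c_out)`` (offset index ``o = 3*di + dj``); the convolution is
    the sum over offsets of a pixelwise channel matmul of the shifted input.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        scale = np.sqrt(2.0 / (c_in * 9))
        self.params["W"] = (rng.standard_normal((9, c_in, c_out)) * scale).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._slices: list[np.ndarray] | None = None

    def forward(self, x, train, rng):
        b, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        weight = self.params["W"]
        out = np.empty((b * h * w, self.c_out), dtype=np.float32)
        out[...] = self.params["b"]
        slices = []
        for o in range(9):
            di, dj = divmod(o, 3)
            sl = np.ascontiguousarray(xp[:, di : di + h, dj : dj + w, :]).reshape(-1, self.c_in)
            out += sl @ weight[o]
            if train:
                slices.append(sl)
        self._slices = slices if train else None
        self._shape = (b, h, w)
        return out.reshape(b, h, w, self.c_out)

    def backward(self, dout):
        b, h, w = self._shape
        d2 = dout.reshape(-1, self.c_out)
        weight = self.params["W"]
        dxp = np.zeros((b, h + 2, w + 2, self.c_in), dtype=np.float32)
        for o in range(9):
            di, dj = divmod(o, 3)
            self.grads["W"][o] = self._slices[o].T @ d2
            dxp[:, di : di + h, dj : dj + w, :] += (d2 @ weight[o].T).reshape(b, h, w, self.c_in)
        self.grads["b"][...] = d2.sum(axis=0)
        self._slices = None
        return dxp[:, 1 : h + 1, 1 : w + 1, :]


class ReLU(Layer):
    def forward(self, x, train, rng):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (spatial dims must be even)."""

    def forward(self, x, train, rng):
        b, h, w, c = x.shape
        v = (
            x.reshape(b, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, h // 2, w // 2, 4, c)
        )
        idx = v.argmax(axis=3)
        if train:
            self._idx, self._shape = idx, (b, h, w, c)
        return np.take_along_axis(v, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dout):
        b, h, w, c = self._shape
        dv = np.zeros((b, h // 2, w // 2, 4, c), dtype=dout.dtype)
        np.put_along_axis(dv, self._idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        return (
            dv.reshape(b, h // 2, w // 2, 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, h, w, c)
        )


class GlobalAvgPool(Layer):
    def forward(self, x, train, rng):
        if train:
            self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        b, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :] / (h * w), (b, h, w, c)).astype(
            dout.dtype
        )


class Dropout(Layer):
    """Inverted dropout: identity at inference time."""

    def __init__(self, p: float) -> None:
        super().__init__()
        self.p = float(p)

    def forward(self, x, train, rng):
        if not train or self.p == 0.0:
            return x
        self._mask = (rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        if self.p == 0.0:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / d_in)
        self.params["W"] = (rng.standard_normal((d_in, d_out)) * scale).astype(np.float32)
        self.params["b"] = np.zeros(d_out, dtype=np.float32)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train, rng):
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"][...] = self._x.T @ dout
        self.grads["b"][...] = dout.sum(axis=0)
        return dout @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits.

    ``targets`` are integer class indices.
    """
    p = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(p.dtype).tiny
    loss = -np.log(p[np.arange(n), targets] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    return float(loss), grad / n


class Network:
    """A plain layer sequence with shared forward/backward traversal."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        if rng is None:
            rng = np.random.default_rng(0)
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def parameters(self):
        """Yield (layer_index, name, param, grad) for every trainable tensor."""
        for i, layer in enumerate(self.layers):
            for name, param in layer.params.items():
                yield i, name, param, layer.grads[name]

    def parameter_count(self) -> int:
        return int(sum(p.size for _, _, p, _ in self.parameters()))

    def get_weights(self) -> dict[str, np.ndarray]:
        return {f"{i}.{name}": p.copy() for i, name, p, _ in self.parameters()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, name, p, _ in self.parameters():
            p[...] = weights[f"{i}.{name}"]


class Adam:
    """Adam with the standard bias correction."""

    def __init__(
        self,
        network: Network,
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.network = network
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {f"{i}.{n}": np.zeros_like(p) for i, n, p, _ in network.parameters()}
        self.v = {f"{i}.{n}": np.zeros_like(p) for i, n, p, _ in network.parameters()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, name, p, g in self.network.parameters():
            key = f"{i}.{name}"
            m, v = self.m[key], self.v[key]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
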