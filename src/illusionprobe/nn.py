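"""A small CPU CNN core: layers, backprop, Adam.

This module implements exactly the pieces the probe needs from a deep
learning framework — strided 2-D convolution (one channel-mixing GEMM
per kernel tap over strided views),
ReLU, max pooling, dropout, dense layers, softmax cross-entropy, and the
Adam optimizer — with explicit forward caches and hand-written gradients.
Every layer is deterministic given the seeds handed to it; intermediate
activations and their gradients are exposed so class-activation maps and
layerwise feature extraction can tap any named point of a network.

Data layout is channels-last (NHWC), float32 throughout: with one
channel-mixing GEMM per kernel tap, channels-last keeps every copy and
accumulation contiguous in memory, which is what CPU throughput is
bound by at these sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "Flatten",
    "Dropout",
    "Linear",
    "Network",
    "Adam",
    "softmax",
    "cross_entropy_with_grad",
]


def _conv_out_hw(h: int, w: int, k: int, stride: int, pad: int) -> tuple[int, int]:
    return (h + 2 * pad - k) // stride + 1, (w + 2 * pad - k) // stride + 1


class Layer:
    """Base layer: forward caches what backward needs."""

    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution with symmetric zero padding, He-initialised.

    Computed by shift-and-multiply: one channel-mixing GEMM per kernel
    tap over strided views of the padded input, which keeps both the
    forward pass and the gradient scatter inside BLAS/vectorised adds.
    Weights are stored as (k, k, in_ch, out_ch); data is NHWC.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        super().__init__()
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, in_ch, out_ch))
        self.params = {"W": w.astype(np.float32), "b": np.zeros(out_ch, np.float32)}

    def _tap(self, xp: np.ndarray, ky: int, kx: int, oh: int, ow: int) -> np.ndarray:
        """Input slice seen by kernel tap (ky, kx), as (n*oh*ow, c)."""
        s = self.stride
        v = xp[:, ky : ky + oh * s : s, kx : kx + ow * s : s, :]
        return np.ascontiguousarray(v).reshape(-1, self.in_ch)

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        p = self.pad
        oh, ow = _conv_out_hw(h, w, self.k, self.stride, p)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))).astype(np.float32, copy=False)
        acc = np.zeros((n * oh * ow, self.out_ch), np.float32)
        W = self.params["W"]
        for ky in range(self.k):
            for kx in range(self.k):
                acc += self._tap(xp, ky, kx, oh, ow) @ W[ky, kx]
        self._cache = (x.shape, xp, oh, ow)
        return acc.reshape(n, oh, ow, self.out_ch) + self.params["b"]

    def backward(self, dout):
        (n, h, w, c), xp, oh, ow = self._cache
        s, p = self.stride, self.pad
        dm = dout.reshape(n * oh * ow, self.out_ch)
        self.grads["b"] = dm.sum(axis=0)
        dW = np.empty_like(self.params["W"])
        dxp = np.zeros_like(xp)
        W = self.params["W"]
        for ky in range(self.k):
            for kx in range(self.k):
                tap = self._tap(xp, ky, kx, oh, ow)
                dW[ky, kx] = tap.T @ dm
                dtap = (dm @ W[ky, kx].T).reshape(n, oh, ow, c)
                dxp[:, ky : ky + oh * s : s, kx : kx + ow * s : s, :] += dtap
        self.grads["W"] = dW
        if p:
            return dxp[:, p:-p, p:-p, :]
        return dxp


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class MaxPool2d(Layer):
    """Non-overlapping k x k max pooling (NHWC); trailing rows/cols dropped."""

    def __init__(self, k: int = 2):
        super().__init__()
        self.k = k

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        k = self.k
        hh, ww = h // k, w // k
        xv = x[:, : hh * k, : ww * k, :].reshape(n, hh, k, ww, k, c)
        xv = xv.transpose(0, 1, 3, 5, 2, 4).reshape(n, hh, ww, c, k * k)
        self._argmax = xv.argmax(axis=-1)
        self._in_shape = x.shape
        return np.ascontiguousarray(xv.max(axis=-1))

    def backward(self, dout):
        n, h, w, c = self._in_shape
        k = self.k
        hh, ww = h // k, w // k
        dx = np.zeros((n, hh, ww, c, k * k), np.float32)
        np.put_along_axis(dx, self._argmax[..., None], dout[..., None], axis=-1)
        dx = dx.reshape(n, hh, ww, c, k, k).transpose(0, 1, 4, 2, 5, 3)
        out = np.zeros(self._in_shape, np.float32)
        out[:, : hh * k, : ww * k, :] = dx.reshape(n, hh * k, ww * k, c)
        return out


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / in_f), size=(in_f, out_f))
        self.params = {"W": w.astype(np.float32), "b": np.zeros(out_f, np.float32)}

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Network:
    """An ordered stack of named layers with tap points.

    ``tap_points`` names layers whose *output* can be captured during the
    forward pass (feature extraction) and whose output gradient can be
    captured during the backward pass (Grad-CAM).
    """

    def __init__(self, layers: list[tuple[str, Layer]], tap_points: list[str]):
        names = [n for n, _ in layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        unknown = set(tap_points) - set(names)
        if unknown:
            raise ValueError(f"tap points {sorted(unknown)} are not layer names")
        self.layers = layers
        self.tap_points = list(tap_points)

    def forward(self, x: np.ndarray, train: bool = False,
                taps: list[str] | None = None):
        """Run the stack; returns (logits, {tap: activation})."""
        want = set(taps or [])
        unknown = want - {n for n, _ in self.layers}
        if unknown:
            raise KeyError(f"unknown layer(s): {sorted(unknown)}")
        captured = {}
        for name, layer in self.layers:
            x = layer.forward(x, train=train)
            if name in want:
                captured[name] = x
        return x, captured

    def backward(self, dlogits: np.ndarray, grad_taps: list[str] | None = None):
        """Backpropagate from the logits; returns {tap: d(out)/d(tap output)}."""
        want = set(grad_taps or [])
        captured = {}
        d = dlogits
        for name, layer in reversed(self.layers):
            if name in want:
                captured[name] = d
            d = layer.backward(d)
        return captured

    def parameters(self):
        out = []
        for name, layer in self.layers:
            for key in layer.params:
                out.append((f"{name}.{key}", layer))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{key}": layer.params[key].copy()
            for name, layer in self.layers
            for key in layer.params
        }

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self.layers:
            for key in layer.params:
                layer.params[key] = state[f"{name}.{key}"].astype(np.float32).copy()

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_with_grad(logits: np.ndarray, labels: np.ndarray):
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


@dataclass
class Adam:
    """Adam with optional decoupled weight decay."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    weight_decay: float = 0.0
    _state: dict = field(default_factory=dict)
    _t: int = 0

    def step(self, network: Network) -> None:
        self._t += 1
        t = self._t
        for full_name, layer in network.parameters():
            key = full_name.rsplit(".", 1)[1]
            g = layer.grads.get(key)
            if g is None:
                continue
            p = layer.params[key]
            if self.weight_decay and p.ndim > 1:
                p -= self.lr * self.weight_decay * p
            if full_name not in self._state:
                self._state[full_name] = (np.zeros_like(p), np.zeros_like(p))
            m, v = self._state[full_name]
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            mh = m / (1 - self.beta1 ** t)
            vh = v / (1 - self.beta2 ** t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)
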