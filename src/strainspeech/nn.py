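"""Minimal numpy neural-network engine for small 3D-convolutional models.

Implements exactly the pieces the word classifier needs — 3D convolution,
instance normalization, ReLU, flatten, fully connected layers, softmax
cross-entropy and Adam — with explicit forward/backward passes so the same
machinery serves training, gradient-based attribution and layer-wise
relevance propagation. Convolutions are evaluated tap-by-tap (one strided
slice + tensordot per kernel offset), which is efficient for the small
spatial grids used here (2 x 4 x T inputs) and keeps the backward pass and
the LRP transpose pass symmetric by construction.

All randomness is injected through an explicit ``numpy.random.Generator``,
so training is bit-reproducible for a fixed seed on one machine.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Conv3d",
    "InstanceNorm3d",
    "ReLU",
    "Flatten",
    "Linear",
    "Network",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


def _triple(v) -> tuple:
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError("expected a scalar or length-3 tuple")
    return t


def conv3d_out_shape(in_shape: tuple, kernel: tuple, pad: tuple, stride: tuple) -> tuple:
    """Per-axis n_out = floor((n_in + 2p - k)/s) + 1."""
    out = []
    for n, k, p, s in zip(in_shape, kernel, pad, stride):
        o = (n + 2 * p - k) // s + 1
        if o < 1 or n + 2 * p < k:
            raise ValueError(
                f"convolution reduces axis below 1: n={n}, k={k}, p={p}, s={s}")
        out.append(o)
    return tuple(out)


def _tap_slices(pad_shape: tuple, out_shape: tuple, offsets: tuple, stride: tuple):
    return tuple(slice(d, d + o * s, s) for d, o, s in zip(offsets, out_shape, stride))


class Layer:
    """Base class: stateless unless it owns parameters."""

    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution over (N, C, H, W, T) with zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel=(3, 3, 3),
                 stride=(1, 1, 1), pad=(1, 1, 1),
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.pad = _triple(pad)
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_channels * int(np.prod(self.kernel))
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       (out_channels, in_channels) + self.kernel)
        self.params = {"W": w, "b": np.zeros(out_channels)}
        self._cache = None

    def out_shape(self, spatial: tuple) -> tuple:
        return conv3d_out_shape(spatial, self.kernel, self.pad, self.stride)

    def _padded(self, x: np.ndarray) -> np.ndarray:
        ph, pw, pt = self.pad
        return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw), (pt, pt)))

    def forward(self, x: np.ndarray) -> np.ndarray:
        w = self.params["W"]
        out_sp = self.out_shape(x.shape[2:])
        xp = self._padded(x)
        out = np.zeros((x.shape[0], self.out_channels) + out_sp)
        kh, kw, kt = self.kernel
        for di in range(kh):
            for dj in range(kw):
                for dk in range(kt):
                    sl = _tap_slices(xp.shape[2:], out_sp, (di, dj, dk), self.stride)
                    xs = xp[(slice(None), slice(None)) + sl]
                    out += np.einsum("ncijk,oc->noijk", xs, w[:, :, di, dj, dk],
                                     optimize=True)
        out += self.params["b"][None, :, None, None, None]
        self._cache = (xp, x.shape, out_sp)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, x_shape, out_sp = self._cache
        w = self.params["W"]
        dW = np.zeros_like(w)
        dxp = np.zeros_like(xp)
        kh, kw, kt = self.kernel
        for di in range(kh):
            for dj in range(kw):
                for dk in range(kt):
                    sl = (slice(None), slice(None)) + _tap_slices(
                        xp.shape[2:], out_sp, (di, dj, dk), self.stride)
                    xs = xp[sl]
                    dW[:, :, di, dj, dk] = np.einsum("noijk,ncijk->oc", dout, xs,
                                                     optimize=True)
                    dxp[sl] += np.einsum("noijk,oc->ncijk", dout,
                                         w[:, :, di, dj, dk], optimize=True)
        self.grads = {"W": dW, "b": dout.sum(axis=(0, 2, 3, 4))}
        ph, pw, pt = self.pad
        _, _, h, wd, t = x_shape
        return dxp[:, :, ph:ph + h, pw:pw + wd, pt:pt + t]

    def input_grad(self, dout: np.ndarray, x_shape: tuple,
                   weight: Optional[np.ndarray] = None) -> np.ndarray:
        """Transpose-convolution of ``dout`` (used by relevance propagation)."""
        w = self.params["W"] if weight is None else weight
        ph, pw, pt = self.pad
        pad_sp = tuple(n + 2 * p for n, p in zip(x_shape[2:], self.pad))
        out_sp = self.out_shape(x_shape[2:])
        dxp = np.zeros((x_shape[0], self.in_channels) + pad_sp)
        kh, kw, kt = self.kernel
        for di in range(kh):
            for dj in range(kw):
                for dk in range(kt):
                    sl = (slice(None), slice(None)) + _tap_slices(
                        pad_sp, out_sp, (di, dj, dk), self.stride)
                    dxp[sl] += np.einsum("noijk,oc->ncijk", dout,
                                         w[:, :, di, dj, dk], optimize=True)
        _, _, h, wd, t = x_shape
        return dxp[:, :, ph:ph + h, pw:pw + wd, pt:pt + t]


class InstanceNorm3d(Layer):
    """Per-sample, per-channel standardization over (H, W, T); no affine."""

    def __init__(self, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (2, 3, 4)
        mean = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv)
        return xhat

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        axes = (2, 3, 4)
        m = dout.mean(axis=axes, keepdims=True)
        mx = (dout * xhat).mean(axis=axes, keepdims=True)
        return inv * (dout - m - xhat * mx)


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Flatten(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), (out_features, in_features))
        self.params = {"W": w, "b": np.zeros(out_features)}
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads = {"W": dout.T @ self._x, "b": dout.sum(axis=0)}
        return dout @ self.params["W"]


class Network:
    """Plain sequential container with explicit backward."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def forward_collect(self, x: np.ndarray) -> list:
        """Forward pass returning the output of every layer (input excluded)."""
        outputs = []
        for layer in self.layers:
            x = layer.forward(x)
            outputs.append(x)
        return outputs

    def backward(self, dout: np.ndarray, upto: int = 0) -> np.ndarray:
        """Backpropagate; stop after layer ``upto`` (returns d(loss)/d(input of upto))."""
        for layer in reversed(self.layers[upto:]):
            dout = layer.backward(dout)
        return dout

    def parameters(self) -> list:
        """Flat list of (layer, name) pairs for every trainable array."""
        return [(layer, name) for layer in self.layers for name in layer.params]

    def state_arrays(self) -> dict:
        """Parameter arrays keyed 'layer{i}.{name}' for checkpointing."""
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                out[f"layer{i}.{name}"] = arr
        return out

    def load_state_arrays(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                key = f"layer{i}.{name}"
                arr = np.asarray(state[key])
                if arr.shape != layer.params[name].shape:
                    raise ValueError(f"shape mismatch for {key}")
                layer.params[name] = arr.copy()


class Adam:
    """Adam optimizer over a list of (layer, param-name) handles."""

    def __init__(self, handles: Sequence[tuple], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.handles = list(handles)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[name]) for layer, name in self.handles]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in self.handles]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, (layer, name) in enumerate(self.handles):
            g = layer.grads[name]
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            layer.params[name] = layer.params[name] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple:
    """Mean cross-entropy loss and gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n
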