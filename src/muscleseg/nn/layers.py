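"""Minimal CPU convolutional-network primitives.

Explicit forward/backward layers over float64 numpy arrays — no autograd
graph, just cached activations and hand-derived gradients. Everything is
single-threaded numpy, so training is bit-deterministic given the seed.
Inputs are (N, C, H, W).
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "Identity",
    "InstanceNorm",
    "Linear",
    "ReLU",
    "GlobalAvgPool",
    "UpsampleNearest",
    "ResBlock",
    "Sequential",
    "fan_in_uniform",
]


DTYPE = np.float32  # single precision: ~2x BLAS throughput, ample for SGD


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


def fan_in_uniform(shape, rng) -> np.ndarray:
    """Fan-in-scaled uniform init, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    if len(shape) >= 2:
        fan_in = int(np.prod(shape[1:]))
    else:
        fan_in = shape[0]
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Base class; children discovered from attribute insertion order."""

    def named_parameters(self, prefix: str = "") -> dict[str, Param]:
        out: dict[str, Param] = {}
        for name, attr in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(attr, Param):
                out[full] = attr
            elif isinstance(attr, Module):
                out.update(attr.named_parameters(prefix=full + "."))
        return out

    def zero_grad(self) -> None:
        for p in self.named_parameters().values():
            p.grad[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.value.copy() for k, p in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        for k, v in state.items():
            if k not in params:
                raise KeyError(f"unknown parameter {k}")
            if params[k].value.shape != v.shape:
                raise ValueError(f"shape mismatch for {k}")
            params[k].value[...] = v

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1, rng=None):
        rng = rng or np.random.default_rng(0)
        self.weight = Param(fan_in_uniform((cout, cin, k, k), rng))
        self.bias = Param(np.zeros(cout))
        self._k, self._stride, self._pad = k, stride, k // 2
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self._k, self._stride, self._pad
        x = np.ascontiguousarray(x, dtype=DTYPE)
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * k * k
        )
        wmat = self.weight.value.reshape(self.weight.value.shape[0], -1)
        y = cols @ wmat.T + self.bias.value
        self._cache = (cols, x.shape, ho, wo)
        return np.ascontiguousarray(
            y.reshape(n, ho * wo, -1).transpose(0, 2, 1).reshape(n, -1, ho, wo)
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape, ho, wo = self._cache
        k, s, p = self._k, self._stride, self._pad
        n, c, h, w = xshape
        cout = dy.shape[1]
        dym = np.ascontiguousarray(
            dy.reshape(n, cout, ho * wo).transpose(0, 2, 1), dtype=DTYPE
        ).reshape(n * ho * wo, cout)
        wmat = self.weight.value.reshape(cout, -1)
        self.weight.grad += (dym.T @ cols).reshape(self.weight.value.shape)
        self.bias.grad += dym.sum(axis=0)
        dcols = (dym @ wmat).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += dcols[
                    :, :, :, :, ki, kj
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.weight = Param(fan_in_uniform((cout, cin), rng))
        self.bias = Param(np.zeros(cout))
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


class InstanceNorm(Module):
    """Per-sample, per-channel standardization over H, W; no learned affine.

    Keeps feature magnitudes O(1) through the network so that transferred
    and freshly initialized layers compose without logit blow-up. Having no
    parameters, it is invisible to name-based weight transfer.
    """

    def __init__(self, eps: float = 1e-5):
        self._eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self._eps)
        self._y = (x - mu) * self._inv
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        y = self._y
        m = dy.mean(axis=(2, 3), keepdims=True)
        my = (dy * y).mean(axis=(2, 3), keepdims=True)
        return (dy - m - y * my) * self._inv


class Identity(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class UpsampleNearest(Module):
    def __init__(self, factor: int = 2):
        self._f = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self._f
        return x.repeat(f, axis=2).repeat(f, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        f = self._f
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // f, f, w // f, f).sum(axis=(3, 5))


class ResBlock(Module):
    """conv-[norm]-relu-conv-[norm] with identity skip, then relu."""

    def __init__(self, channels: int, rng=None, use_norm: bool = False):
        self.conv1 = Conv2d(channels, channels, 3, rng=rng)
        self.norm1 = InstanceNorm() if use_norm else Identity()
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, 3, rng=rng)
        self.norm2 = InstanceNorm() if use_norm else Identity()
        self.relu_out = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.norm2(self.conv2(self.relu1(self.norm1(self.conv1(x)))))
        return self.relu_out(x + y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dy)
        dres = self.conv1.backward(
            self.norm1.backward(
                self.relu1.backward(self.conv2.backward(self.norm2.backward(d)))
            )
        )
        return d + dres


class Sequential(Module):
    def __init__(self, **layers: Module):
        for name, layer in layers.items():
            setattr(self, name, layer)
        self._order = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for name in self._order:
            x = getattr(self, name)(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for name in reversed(self._order):
            dy = getattr(self, name).backward(dy)
        return dy
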