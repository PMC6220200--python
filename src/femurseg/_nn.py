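"""Minimal NumPy layer kernels with explicit forward/backward passes.

Layout is channels-last: a 2D feature map has shape ``(H, W, C)`` and a 3D
one ``(H, W, D, C)``. Every layer caches what its backward pass needs; call
``forward`` then ``backward`` in LIFO order. Parameters and their gradients
live on the layer as ``params[name]`` / ``grads[name]``.

Convolutions are evaluated as a sum over kernel taps — one channel-mixing
matmul per tap — which keeps peak memory at one feature map rather than an
im2col buffer.
"""

from __future__ import annotations

from itertools import product
from typing import Dict, List, Tuple

import numpy as np

DTYPE = np.float32


class ShapeError(ValueError):
    """Raised when an input shape is inadmissible for a layer or network."""


class Layer:
    def __init__(self) -> None:
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


def xavier_uniform(rng: np.random.Generator, shape: Tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier uniform initialization: keeps gradient scale roughly
    constant across layers."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Conv(Layer):
    """k^dims convolution (k=3 by default, k=1 for the output head) with
    optional dilation; 'same' zero padding when ``padded`` else valid."""

    def __init__(self, dims: int, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3, dilation: int = 1, padded: bool = True,
                 bias_init: float = 0.10, relu: bool = True) -> None:
        super().__init__()
        self.dims, self.c_in, self.c_out = dims, c_in, c_out
        self.k, self.dilation, self.padded, self.relu = k, dilation, padded, relu
        taps = k ** dims
        self.params["W"] = xavier_uniform(rng, (taps, c_in, c_out),
                                          fan_in=c_in * taps, fan_out=c_out * taps)
        self.params["b"] = np.full((c_out,), bias_init, dtype=DTYPE)
        self.zero_grad()
        self._offsets = list(product(range(k), repeat=dims))

    def forward(self, x: np.ndarray) -> np.ndarray:
        d = self.dilation
        halo = (self.k - 1) * d // 2 if self.k > 1 else 0
        if self.k == 1:
            self._x = x
            y = x @ self.params["W"][0] + self.params["b"]
            return np.maximum(y, 0, out=y) if self.relu else y
        if self.padded:
            pad = [(halo, halo)] * self.dims + [(0, 0)]
            xp = np.pad(x, pad)
        else:
            xp = x
            if any(s <= 2 * halo for s in x.shape[:-1]):
                raise ShapeError(f"input spatial shape {x.shape[:-1]} too small for "
                                 f"valid {self.k}^d conv with dilation {d}")
        out_spatial = tuple(s - 2 * halo for s in xp.shape[:-1])
        self._xp = xp
        self._out_spatial = out_spatial
        W = self.params["W"]
        y = np.empty(out_spatial + (self.c_out,), dtype=DTYPE)
        y[...] = self.params["b"]
        for t, off in enumerate(self._offsets):
            sl = tuple(slice(o * d, o * d + n) for o, n in zip(off, out_spatial))
            y += xp[sl] @ W[t]
        if self.relu:
            self._pre = y
            y = np.maximum(y, 0)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.relu:
            dy = dy * (self._pre > 0)
        W = self.params["W"]
        self.grads["b"] += dy.reshape(-1, self.c_out).sum(axis=0)
        if self.k == 1:
            x = self._x
            self.grads["W"][0] += x.reshape(-1, self.c_in).T @ dy.reshape(-1, self.c_out)
            return (dy @ W[0].T).astype(DTYPE)
        d = self.dilation
        halo = (self.k - 1) * d // 2
        xp = self._xp
        out_spatial = self._out_spatial
        dxp = np.zeros_like(xp)
        dyf = dy.reshape(-1, self.c_out)
        for t, off in enumerate(self._offsets):
            sl = tuple(slice(o * d, o * d + n) for o, n in zip(off, out_spatial))
            self.grads["W"][t] += xp[sl].reshape(-1, self.c_in).T @ dyf
            dxp[sl] += dy @ W[t].T
        self._xp = None
        if self.padded:
            core = tuple(slice(halo, s - halo) for s in xp.shape[:-1])
            return dxp[core]
        return dxp


class MaxPool(Layer):
    """2^dims max-pooling with stride 2; requires even spatial extents."""

    def __init__(self, dims: int) -> None:
        super().__init__()
        self.dims = dims

    def forward(self, x: np.ndarray) -> np.ndarray:
        spatial = x.shape[:-1]
        if any(s % 2 for s in spatial) or any(s < 2 for s in spatial):
            raise ShapeError(f"max-pool needs even spatial extents, got {spatial}")
        c = x.shape[-1]
        out_sp = tuple(s // 2 for s in spatial)
        shape = []
        for s in out_sp:
            shape += [s, 2]
        shape.append(c)
        xr = x.reshape(shape)
        # bring the window axes (1, 3, [5]) to the back, flatten them
        win_axes = tuple(range(1, 2 * self.dims, 2))
        keep_axes = tuple(range(0, 2 * self.dims, 2)) + (2 * self.dims,)
        xt = np.transpose(xr, keep_axes + win_axes)
        xt = xt.reshape(out_sp + (c, 2 ** self.dims))
        self._argmax = np.argmax(xt, axis=-1)
        y = np.take_along_axis(xt, self._argmax[..., None], axis=-1)[..., 0]
        self._in_spatial = spatial
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c = dy.shape[-1]
        out_sp = dy.shape[:-1]
        flat = np.zeros(out_sp + (c, 2 ** self.dims), dtype=DTYPE)
        np.put_along_axis(flat, self._argmax[..., None], dy[..., None], axis=-1)
        # invert the transpose/reshape of forward
        xt = flat.reshape(out_sp + (c,) + (2,) * self.dims)
        n = self.dims
        # current axes: (s0..s{n-1}, c, w0..w{n-1}) -> interleave (s0,w0,s1,w1,...,c)
        order = []
        for i in range(n):
            order += [i, n + 1 + i]
        order.append(n)
        xi = np.transpose(xt, order)
        return xi.reshape(self._in_spatial + (c,))


class UpConv(Layer):
    """Transposed convolution, kernel 2^dims, stride 2: doubles spatial
    extent; conventionally halves the channel count."""

    def __init__(self, dims: int, c_in: int, c_out: int, rng: np.random.Generator,
                 bias_init: float = 0.10, relu: bool = True) -> None:
        super().__init__()
        self.dims, self.c_in, self.c_out, self.relu = dims, c_in, c_out, relu
        taps = 2 ** dims
        self.params["W"] = xavier_uniform(rng, (taps, c_in, c_out),
                                          fan_in=c_in, fan_out=c_out * taps)
        self.params["b"] = np.full((c_out,), bias_init, dtype=DTYPE)
        self.zero_grad()
        self._offsets = list(product(range(2), repeat=dims))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        out_sp = tuple(2 * s for s in x.shape[:-1])
        W = self.params["W"]
        y = np.empty(out_sp + (self.c_out,), dtype=DTYPE)
        y[...] = self.params["b"]
        for t, off in enumerate(self._offsets):
            sl = tuple(slice(o, None, 2) for o in off)
            y[sl] = x @ W[t] + self.params["b"]
        if self.relu:
            self._pre = y
            y = np.maximum(y, 0)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.relu:
            dy = dy * (self._pre > 0)
        x = self._x
        W = self.params["W"]
        dx = np.zeros_like(x)
        xf = x.reshape(-1, self.c_in)
        for t, off in enumerate(self._offsets):
            sl = tuple(slice(o, None, 2) for o in off)
            dyt = dy[sl]
            self.grads["W"][t] += xf.T @ dyt.reshape(-1, self.c_out)
            self.grads["b"] += dyt.reshape(-1, self.c_out).sum(axis=0)
            dx += dyt @ W[t].T
        return dx


def center_crop(x: np.ndarray, spatial: Tuple[int, ...]) -> Tuple[np.ndarray, Tuple[slice, ...]]:
    """Center-crop a channels-last feature map to the given spatial shape."""
    sl = []
    for have, want in zip(x.shape[:-1], spatial):
        if have < want:
            raise ShapeError(f"cannot crop {x.shape[:-1]} to {spatial}")
        lo = (have - want) // 2
        sl.append(slice(lo, lo + want))
    sl = tuple(sl)
    return x[sl], sl


def softmax2(logits: np.ndarray) -> np.ndarray:
    """Per-voxel softmax over the trailing 2-channel axis; returns the
    foreground (channel 1) probability."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    return p[..., 1]


def adam_step(params: List[np.ndarray], grads: List[np.ndarray],
              m: List[np.ndarray], v: List[np.ndarray], t: int, lr: float,
              beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
    """In-place Adam update (canonical defaults)."""
    b1t = 1.0 - beta1 ** t
    b2t = 1.0 - beta2 ** t
    for p, g, mi, vi in zip(params, grads, m, v):
        mi *= beta1
        mi += (1 - beta1) * g
        vi *= beta2
        vi += (1 - beta2) * (g * g)
        p -= lr * (mi / b1t) / (np.sqrt(vi / b2t) + eps)
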