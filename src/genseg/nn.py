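"""Neural-network building blocks on top of :mod:`genseg.autodiff`.

Layers are purely functional: parameters live in plain ``dict[str, Tensor]``
containers and every forward function takes the tensors it needs explicitly.
This style makes "virtual" parameter updates trivial — a one-step-updated
parameter set is just another dict of graph tensors, and running the model
with it keeps the dependence on upstream quantities differentiable.

Convolution and transposed convolution are expressed with an im2col/col2im
gather–scatter pair plus a batched matmul, so arbitrary-order gradients are
available (required by the architecture hypergradient).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "pad2d",
    "conv2d",
    "conv_transpose2d",
    "instance_norm",
    "leaky_relu",
    "relu",
    "activation",
    "kaiming_conv_init",
    "SGD",
    "Adam",
    "RMSprop",
    "ReduceLROnPlateau",
]


# -- index plans (constants; cached per geometry) -----------------------

@lru_cache(maxsize=256)
def _pad_indices(n, c, h, w, p):
    """Flat positions of the (n,c,h,w) block inside the zero-padded array."""
    hp, wp = h + 2 * p, w + 2 * p
    ni, ci, hi, wi = np.ix_(np.arange(n), np.arange(c), np.arange(h) + p, np.arange(w) + p)
    return (((ni * c + ci) * hp + hi) * wp + wi), (n, c, hp, wp)


@lru_cache(maxsize=256)
def _im2col_indices(n, c, hp, wp, kh, kw, stride):
    """Flat indices into an (n,c,hp,wp) array → columns (n, c*kh*kw, oh*ow)."""
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    ci, ki, kj = np.meshgrid(np.arange(c), np.arange(kh), np.arange(kw), indexing="ij")
    oi, oj = np.meshgrid(np.arange(oh), np.arange(ow), indexing="ij")
    rows = ki.reshape(-1, 1) + stride * oi.reshape(1, -1)   # (c*kh*kw, oh*ow)
    cols = kj.reshape(-1, 1) + stride * oj.reshape(1, -1)
    chan = ci.reshape(-1, 1)
    base = (chan * hp + rows) * wp + cols                   # within one sample
    ni = np.arange(n).reshape(n, 1, 1) * (c * hp * wp)
    return ni + base[None], (oh, ow)


def pad2d(x: Tensor, p: int) -> Tensor:
    """Zero-pad the two trailing spatial axes of an (N,C,H,W) tensor."""
    if p == 0:
        return x
    n, c, h, w = x.shape
    idx, padded_shape = _pad_indices(n, c, h, w, p)
    flat = ad.scatter_flat(ad.reshape(x, idx.shape), idx, int(np.prod(padded_shape)))
    return ad.reshape(flat, padded_shape)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int, padding: int) -> Tensor:
    """2-D convolution (cross-correlation); x (N,C,H,W), w (O,C,kh,kw)."""
    n, c, h, wd = x.shape
    o, c2, kh, kw = w.shape
    if c2 != c:
        raise ValueError(f"conv2d: input has {c} channels, kernel expects {c2}")
    xp = pad2d(x, padding)
    _, _, hp, wp = xp.shape
    idx, (oh, ow) = _im2col_indices(n, c, hp, wp, kh, kw, stride)
    cols = ad.gather_flat(xp, idx)                       # (N, C*kh*kw, oh*ow)
    wmat = ad.reshape(w, (o, c * kh * kw))
    y = ad.matmul(wmat, cols)                            # (N, O, oh*ow)
    if b is not None:
        y = ad.add(y, ad.reshape(b, (1, o, 1)))
    return ad.reshape(y, (n, o, oh, ow))


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int, padding: int) -> Tensor:
    """2-D transposed convolution; x (N,C,H,W), w (C,O,kh,kw).

    Output spatial size is ``(H-1)*stride - 2*padding + k``; for the
    kernel pools used here (k - 2p = s) that is exactly ``H*stride``.
    """
    n, c, h, wd = x.shape
    c2, o, kh, kw = w.shape
    if c2 != c:
        raise ValueError(f"conv_transpose2d: input has {c} channels, kernel expects {c2}")
    hp = (h - 1) * stride + kh
    wp = (wd - 1) * stride + kw
    idx, _ = _im2col_indices(n, o, hp, wp, kh, kw, stride)   # adjoint plan
    wmat = ad.transpose(ad.reshape(w, (c, o * kh * kw)), (1, 0))
    cols = ad.matmul(wmat, ad.reshape(x, (n, c, h * wd)))    # (N, O*kh*kw, H*W)
    flat = ad.scatter_flat(cols, idx, n * o * hp * wp)
    y = ad.reshape(flat, (n, o, hp, wp))
    if padding > 0:
        y = y[:, :, padding:hp - padding, padding:wp - padding]
    if b is not None:
        y = ad.add(y, ad.reshape(b, (1, o, 1, 1)))
    return y


def instance_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel spatial standardization (no affine terms)."""
    mu = ad.mean(x, axis=(2, 3), keepdims=True)
    xc = ad.sub(x, mu)
    var = ad.mean(ad.mul(xc, xc), axis=(2, 3), keepdims=True)
    return ad.div(xc, ad.sqrt(ad.add(var, Tensor(eps))))


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    mask = (x.data > 0).astype(x.dtype)
    return ad.mul(x, Tensor(mask + slope * (1.0 - mask)))


def relu(x: Tensor) -> Tensor:
    return ad.mul(x, Tensor((x.data > 0).astype(x.dtype)))


def activation(x: Tensor, kind: str) -> Tensor:
    """Dispatch on name; 'tanh'/'softplus' are smooth (used by gradient checks)."""
    if kind == "lrelu":
        return leaky_relu(x)
    if kind == "relu":
        return relu(x)
    if kind == "tanh":
        return ad.tanh(x)
    if kind == "softplus":
        return ad.softplus(x)
    if kind in ("identity", "none"):
        return x
    raise ValueError(f"unknown activation {kind!r}")


def kaiming_conv_init(rng: np.random.Generator, shape, fan_in: int, dtype=np.float64) -> np.ndarray:
    """He-style normal initialization for convolution kernels."""
    std = np.sqrt(2.0 / max(fan_in, 1))
    return (rng.standard_normal(shape) * std).astype(dtype)


# -- optimizers over parameter dicts ------------------------------------

class SGD:
    """Plain gradient descent with optional momentum, on a name→Tensor dict."""

    def __init__(self, params: dict, lr: float, momentum: float = 0.0, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._buf = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self, grads: dict):
        for k, p in self.params.items():
            g = grads[k].data + self.weight_decay * p.data
            if self.momentum:
                self._buf[k] = self.momentum * self._buf[k] + g
                g = self._buf[k]
            p.data = p.data - self.lr * g


class Adam:
    def __init__(self, params: dict, lr: float, betas=(0.9, 0.999),
                 weight_decay: float = 0.0, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.weight_decay = weight_decay
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self._v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self, grads: dict):
        self.t += 1
        for k, p in self.params.items():
            g = grads[k].data + self.weight_decay * p.data
            self._m[k] = self.b1 * self._m[k] + (1 - self.b1) * g
            self._v[k] = self.b2 * self._v[k] + (1 - self.b2) * g * g
            mhat = self._m[k] / (1 - self.b1 ** self.t)
            vhat = self._v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSprop:
    """RMSprop with momentum, matching the common square-average formulation."""

    def __init__(self, params: dict, lr: float, momentum: float = 0.0,
                 alpha: float = 0.99, weight_decay: float = 0.0, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.alpha = alpha
        self.weight_decay = weight_decay
        self.eps = eps
        self._sq = {k: np.zeros_like(v.data) for k, v in params.items()}
        self._buf = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self, grads: dict):
        for k, p in self.params.items():
            g = grads[k].data + self.weight_decay * p.data
            self._sq[k] = self.alpha * self._sq[k] + (1 - self.alpha) * g * g
            upd = g / (np.sqrt(self._sq[k]) + self.eps)
            if self.momentum:
                self._buf[k] = self.momentum * self._buf[k] + upd
                upd = self._buf[k]
            p.data = p.data - self.lr * upd


class ReduceLROnPlateau:
    """Halve the learning rate when a maximized metric stops improving."""

    def __init__(self, optimizer, patience: int = 2, factor: float = 0.5, mode: str = "max"):
        self.opt = optimizer
        self.patience = patience
        self.factor = factor
        self.mode = mode
        self.best = -np.inf if mode == "max" else np.inf
        self.bad = 0

    def step(self, metric: float):
        improved = metric > self.best if self.mode == "max" else metric < self.best
        if improved:
            self.best = metric
            self.bad = 0
        else:
            self.bad += 1
            if self.bad > self.patience:
                self.opt.lr *= self.factor
                self.bad = 0
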