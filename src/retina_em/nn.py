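"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical core the segmentation network is built on: a small
tape-based autodiff engine providing exactly the operations the hybrid
CNN-transformer needs (dense and 2-D convolution layers, attention-style
batched matmul, layer normalisation, softmax/log-softmax, nearest-neighbour
upsampling, concatenation).  All computation is float32 numpy; determinism
follows from seeding a single ``numpy.random.Generator`` per run.

Gradients accumulate into ``Tensor.grad``; ``backward`` walks the tape in
reverse topological order.  Only tensors created with ``requires_grad=True``
(parameters) or depending on one retain gradients.
"""

from __future__ import annotations

from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

Array = np.ndarray


def _as_f32(x) -> Array:
    return np.asarray(x, dtype=np.float32)


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data: Array = _as_f32(data)
        self.grad: Optional[Array] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[Array], None]] = None
        self._parents: Tuple["Tensor", ...] = ()

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- graph machinery -----------------------------------------------------
    def _accumulate(self, g: Array) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: Optional[Array] = None) -> None:
        """Backpropagate from this tensor (default seed gradient: ones)."""
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(_as_f32(grad))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # operator sugar
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)


def _needs_grad(*ts) -> bool:
    return any(isinstance(t, Tensor) and (t.requires_grad or t._parents or t._backward)
               for t in ts)


def _make(data: Array, parents: Sequence[Tensor],
          backward: Optional[Callable[[Array], None]]) -> Tensor:
    out = Tensor(data)
    if backward is not None and _needs_grad(*parents):
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
        out._backward = backward
    return out


def _unbroadcast(g: Array, shape: Tuple[int, ...]) -> Array:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / reduction ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b) -> Tensor:
    bb = b if isinstance(b, Tensor) else Tensor(b)

    def bw(g: Array) -> None:
        a._accumulate(_unbroadcast(g, a.shape))
        bb._accumulate(_unbroadcast(g, bb.shape))

    return _make(a.data + bb.data, (a, bb), bw)


def mul(a: Tensor, b) -> Tensor:
    if not isinstance(b, Tensor):
        s = _as_f32(b)

        def bw_s(g: Array) -> None:
            a._accumulate(_unbroadcast(g * s, a.shape))

        return _make(a.data * s, (a,), bw_s)

    def bw(g: Array) -> None:
        a._accumulate(_unbroadcast(g * b.data, a.shape))
        b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(a.data * b.data, (a, b), bw)


def reciprocal(a: Tensor) -> Tensor:
    y = 1.0 / a.data

    def bw(g: Array) -> None:
        a._accumulate(-g * y * y)

    return _make(y, (a,), bw)


def square(a: Tensor) -> Tensor:
    def bw(g: Array) -> None:
        a._accumulate(g * (2.0 * a.data))

    return _make(a.data * a.data, (a,), bw)


def mean(a: Tensor) -> Tensor:
    n = a.data.size

    def bw(g: Array) -> None:
        a._accumulate(np.full_like(a.data, float(g) / n))

    return _make(np.float32(a.data.mean()), (a,), bw)


def sum_all(a: Tensor) -> Tensor:
    def bw(g: Array) -> None:
        a._accumulate(np.full_like(a.data, float(g)))

    return _make(np.float32(a.data.sum()), (a,), bw)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bw(g: Array) -> None:
        a._accumulate(g * mask)

    return _make(a.data * mask, (a,), bw)


def gelu(a: Tensor) -> Tensor:
    """tanh-approximation GELU (the transformer MLP nonlinearity)."""
    x = a.data
    c = np.float32(np.sqrt(2.0 / np.pi))
    inner = c * (x + 0.044715 * x ** 3)
    t = np.tanh(inner)
    y = 0.5 * x * (1.0 + t)

    def bw(g: Array) -> None:
        dt = (1.0 - t * t) * c * (1.0 + 3 * 0.044715 * x * x)
        a._accumulate(g * (0.5 * (1.0 + t) + 0.5 * x * dt))

    return _make(y, (a,), bw)


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(a: Tensor, shape: Tuple[int, ...]) -> Tensor:
    orig = a.shape

    def bw(g: Array) -> None:
        a._accumulate(g.reshape(orig))

    return _make(a.data.reshape(shape), (a,), bw)


def transpose(a: Tensor, axes: Tuple[int, ...]) -> Tensor:
    inv = np.argsort(axes)

    def bw(g: Array) -> None:
        a._accumulate(g.transpose(inv))

    return _make(a.data.transpose(axes), (a,), bw)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g: Array) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), bw)


# ---------------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matmul with numpy broadcasting over leading axes."""

    def bw(g: Array) -> None:
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        a._accumulate(_unbroadcast(ga, a.shape))
        b._accumulate(_unbroadcast(gb, b.shape))

    return _make(np.matmul(a.data, b.data), (a, b), bw)


def softmax(a: Tensor) -> Tensor:
    """Softmax over the last axis."""
    x = a.data - a.data.max(axis=-1, keepdims=True)
    e = np.exp(x)
    y = e / e.sum(axis=-1, keepdims=True)

    def bw(g: Array) -> None:
        dot = (g * y).sum(axis=-1, keepdims=True)
        a._accumulate(y * (g - dot))

    return _make(y, (a,), bw)


def log_softmax(a: Tensor) -> Tensor:
    x = a.data - a.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(x).sum(axis=-1, keepdims=True))
    y = x - lse

    def bw(g: Array) -> None:
        a._accumulate(g - np.exp(y) * g.sum(axis=-1, keepdims=True))

    return _make(y, (a,), bw)


def layer_norm(a: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis with learned affine."""
    x = a.data
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    y = xhat * weight.data + bias.data
    n = x.shape[-1]

    def bw(g: Array) -> None:
        gxhat = g * weight.data
        gvar = (gxhat * xc).sum(axis=-1, keepdims=True) * (-0.5) * inv ** 3
        gmu = (-gxhat * inv).sum(axis=-1, keepdims=True) + gvar * (-2.0 / n) * xc.sum(axis=-1, keepdims=True)
        ga = gxhat * inv + gvar * 2.0 / n * xc + gmu / n
        a._accumulate(ga)
        weight._accumulate(_unbroadcast(g * xhat, weight.shape))
        bias._accumulate(_unbroadcast(g, bias.shape))

    return _make(y, (a, weight, bias), bw)


# ---------------------------------------------------------------------------
# image ops (NCHW)
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor], stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D convolution, NCHW layout, square kernel.

    Implemented as a sum over kernel offsets of strided einsums; exact for
    the small kernels (1x1, 3x3, patch-size) the network uses.
    """
    B, C, H, W = x.shape
    O, C2, K, _ = w.shape
    if C2 != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {C2}")
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - K) // stride + 1
    Wo = (Wp - K) // stride + 1
    out = np.zeros((B, O, Ho, Wo), dtype=np.float32)
    for di in range(K):
        for dj in range(K):
            patch = xp[:, :, di:di + stride * Ho:stride, dj:dj + stride * Wo:stride]
            out += np.einsum("oc,bchw->bohw", w.data[:, :, di, dj], patch,
                             optimize=True)
    if b is not None:
        out += b.data.reshape(1, O, 1, 1)

    def bw(g: Array) -> None:
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        for di in range(K):
            for dj in range(K):
                patch = xp[:, :, di:di + stride * Ho:stride, dj:dj + stride * Wo:stride]
                gw[:, :, di, dj] = np.einsum("bohw,bchw->oc", g, patch, optimize=True)
                gxp[:, :, di:di + stride * Ho:stride, dj:dj + stride * Wo:stride] += \
                    np.einsum("oc,bohw->bchw", w.data[:, :, di, dj], g, optimize=True)
        if padding:
            gx = gxp[:, :, padding:padding + H, padding:padding + W]
        else:
            gx = gxp
        x._accumulate(gx)
        w._accumulate(gw)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, bw)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling (NCHW)."""
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)
    B, C, H, W = x.shape

    def bw(g: Array) -> None:
        x._accumulate(g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)))

    return _make(y, (x,), bw)


def instance_norm(x: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel spatial normalisation with learned affine.

    Used in the convolutional stages; unlike batch norm it has no running
    statistics, so train and eval behaviour are identical and deterministic.
    """
    B, C, H, W = x.shape
    xd = x.data
    mu = xd.mean(axis=(2, 3), keepdims=True)
    xc = xd - mu
    var = (xc * xc).mean(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    wv = weight.data.reshape(1, C, 1, 1)
    y = xhat * wv + bias.data.reshape(1, C, 1, 1)
    n = H * W

    def bw(g: Array) -> None:
        gxhat = g * wv
        gvar = (gxhat * xc).sum(axis=(2, 3), keepdims=True) * (-0.5) * inv ** 3
        gmu = (-gxhat * inv).sum(axis=(2, 3), keepdims=True) + \
            gvar * (-2.0 / n) * xc.sum(axis=(2, 3), keepdims=True)
        gx = gxhat * inv + gvar * 2.0 / n * xc + gmu / n
        x._accumulate(gx)
        weight._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        bias._accumulate(g.sum(axis=(0, 2, 3)))

    return _make(y, (x, weight, bias), bw)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    """A trainable tensor; ``trainable`` can be cleared to freeze it."""

    __slots__ = ("trainable",)

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.trainable = True


def kaiming_conv(rng: np.random.Generator, o: int, c: int, k: int) -> Parameter:
    fan_in = c * k * k
    sd = np.sqrt(2.0 / fan_in)
    return Parameter(rng.normal(0.0, sd, size=(o, c, k, k)))


def xavier_linear(rng: np.random.Generator, n_in: int, n_out: int) -> Parameter:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return Parameter(rng.uniform(-limit, limit, size=(n_in, n_out)))


def zeros(*shape: int) -> Parameter:
    return Parameter(np.zeros(shape, dtype=np.float32))


def ones(*shape: int) -> Parameter:
    return Parameter(np.ones(shape, dtype=np.float32))


class SGD:
    """Stochastic gradient descent with momentum and optional polynomial
    learning-rate decay (``lr_t = lr0 * (1 - t/T)**power``)."""

    def __init__(self, params: Dict[str, Parameter], lr: float,
                 momentum: float = 0.9, total_iters: Optional[int] = None,
                 poly_power: float = 0.9):
        self.params = params
        self.lr0 = lr
        self.momentum = momentum
        self.total_iters = total_iters
        self.poly_power = poly_power
        self.t = 0
        self.velocity: Dict[str, Array] = {
            k: np.zeros_like(p.data) for k, p in params.items()
        }

    def current_lr(self) -> float:
        if self.total_iters is None:
            return self.lr0
        frac = min(self.t / self.total_iters, 1.0 - 1e-9)
        return self.lr0 * (1.0 - frac) ** self.poly_power

    def step(self) -> None:
        lr = self.current_lr()
        for k, p in self.params.items():
            if not p.trainable or p.grad is None:
                continue
            v = self.velocity[k]
            v *= self.momentum
            v -= lr * p.grad
            p.data += v
        self.t += 1

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def numerical_grad(f: Callable[[], Tensor], p: Tensor, eps: float = 1e-3) -> Array:
    """Central-difference gradient of scalar ``f()`` w.r.t. ``p`` (test oracle)."""
    g = np.zeros_like(p.data, dtype=np.float64)
    flat = p.data.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        old = flat[i]
        flat[i] = old + eps
        hi = float(f().data)
        flat[i] = old - eps
        lo = float(f().data)
        flat[i] = old
        gf[i] = (hi - lo) / (2 * eps)
    return g.astype(np.float32)
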