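"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the compute core behind the package's encoder-decoder networks.  It
implements exactly the operations those networks need — N-dimensional "same"
convolution, kernel-2 transposed convolution, max pooling, ELU/ReLU/sigmoid,
dropout, batch normalisation, dense layers for squeeze-excitation gating,
concatenation and broadcast arithmetic — each with a hand-written
vector-Jacobian product, plus SGD with momentum.

Arrays are laid out channel-first with a leading batch axis: ``(B, C, Y, X)``
in 2D and ``(B, C, Z, Y, X)`` in 3D.  Everything runs in float32; gradient
accumulation inside a single op uses the same precision (the networks are
small enough that this is not a concern at the patch sizes used here).

The engine is deliberately tape-based and eager: every op returns a new
:class:`Tensor` holding its value, its parents and a closure computing the
parent gradients.  ``backward(loss)`` walks the tape in reverse topological
order.  On CPU the whole pipeline is bit-deterministic for a fixed seed,
which is what the stability harness relies on.
"""

from __future__ import annotations

import contextlib
import itertools
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "backward",
    "conv_nd",
    "conv_transpose_nd",
    "max_pool",
    "elu",
    "relu",
    "sigmoid",
    "dropout",
    "batch_norm",
    "dense",
    "concat",
    "add",
    "mul",
    "reshape",
    "global_avg_pool",
    "bce_loss",
    "SGD",
    "he_normal",
    "glorot_uniform",
]


class Tensor:
    """A node in the autodiff tape.

    Parameters are ``Tensor`` objects with ``trainable=True``; intermediate
    results carry their parents and a vjp closure.
    """

    __slots__ = ("value", "grad", "parents", "vjp", "trainable", "name")

    def __init__(
        self,
        value: np.ndarray,
        parents: tuple["Tensor", ...] = (),
        vjp: Callable[[np.ndarray], tuple[np.ndarray, ...]] | None = None,
        trainable: bool = False,
        name: str = "",
    ):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self.vjp = vjp
        self.trainable = trainable
        self.name = name

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    @property
    def size(self) -> int:
        return int(self.value.size)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(name={self.name!r}, shape={self.value.shape}, trainable={self.trainable})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable tape construction (inference mode; frees activations eagerly)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def backward(root: Tensor) -> None:
    """Accumulate gradients of ``root`` (summed to a scalar) into the tape."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))
    root.grad = np.ones_like(root.value)
    for node in reversed(topo):
        if node.vjp is None or node.grad is None:
            continue
        grads = node.vjp(node.grad)
        for parent, g in zip(node.parents, grads):
            if g is None:
                continue
            if parent.grad is None:
                parent.grad = g.astype(np.float32, copy=True)
            else:
                parent.grad += g


def zero_grad(tensors: Sequence[Tensor]) -> None:
    for t in tensors:
        t.grad = None


# ---------------------------------------------------------------------------
# initialisers
# ---------------------------------------------------------------------------

def he_normal(shape: tuple[int, ...], fan_in: int, fan_out: int, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def glorot_uniform(shape: tuple[int, ...], fan_in: int, fan_out: int, rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def conv_nd(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """N-d convolution, stride 1, zero "same" padding.

    ``x``: (B, Cin, *spatial); ``w``: (Cout, Cin, *kernel); ``b``: (Cout,).
    Implemented as a sum over kernel offsets of channel-mixing matmuls so the
    heavy lifting stays in BLAS.
    """
    xv, wv, bv = x.value, w.value, b.value
    B, cin = xv.shape[:2]
    spatial = xv.shape[2:]
    kernel = wv.shape[2:]
    cout = wv.shape[0]
    n = int(np.prod(spatial))
    pad = [(0, 0), (0, 0)] + [((k - 1) // 2, k // 2) for k in kernel]
    xp = np.pad(xv, pad)

    def _view(idx):
        sl = (slice(None), slice(None)) + tuple(
            slice(i, i + s) for i, s in zip(idx, spatial)
        )
        return np.ascontiguousarray(xp[sl]).reshape(B, cin, n)

    offsets = list(itertools.product(*(range(k) for k in kernel)))
    out = np.zeros((B, cout, n), dtype=np.float32)
    for idx in offsets:
        out += np.matmul(wv[(slice(None), slice(None)) + idx], _view(idx))
    outv = out.reshape(B, cout, *spatial) + bv.reshape((1, cout) + (1,) * len(spatial))
    if not grad_enabled():
        return Tensor(outv)

    def vjp(g: np.ndarray):
        gf = g.reshape(B, cout, n)
        db = gf.sum(axis=(0, 2))
        dw = np.zeros_like(wv)
        dxp = np.zeros_like(xp)
        for idx in offsets:
            view = _view(idx)  # recomputed: cheaper than caching all offsets
            dw[(slice(None), slice(None)) + idx] = np.einsum(
                "bon,bcn->oc", gf, view, optimize=True
            )
            sl = (slice(None), slice(None)) + tuple(
                slice(i, i + s) for i, s in zip(idx, spatial)
            )
            dxp[sl] += np.matmul(
                wv[(slice(None), slice(None)) + idx].T, gf
            ).reshape(B, cin, *spatial)
        crop = (slice(None), slice(None)) + tuple(
            slice(p[0], p[0] + s) for p, s in zip(pad[2:], spatial)
        )
        return dxp[crop], dw, db

    return Tensor(outv, (x, w, b), vjp)


def conv_transpose_nd(x: Tensor, w: Tensor, b: Tensor, factors: tuple[int, ...]) -> Tensor:
    """Transposed convolution with kernel = stride = ``factors`` per axis.

    With kernel equal to stride the output blocks do not overlap, so each
    output ``factors``-block is a plain linear map of one input voxel.
    ``w``: (Cout, Cin, *factors).
    """
    xv, wv, bv = x.value, w.value, b.value
    B, cin = xv.shape[:2]
    spatial = xv.shape[2:]
    cout = wv.shape[0]
    nd = len(spatial)
    f = tuple(factors)
    n = int(np.prod(spatial))
    xf = xv.reshape(B, cin, n)
    wf = wv.reshape(cout, cin, -1)  # (cout, cin, F)
    t = np.einsum("ocf,bcn->bofn", wf, xf, optimize=True)  # (B,cout,F,n)
    t = t.reshape((B, cout) + f + spatial)
    # interleave: (B, cout, s0, f0, s1, f1, ...)
    perm = [0, 1]
    for ax in range(nd):
        perm += [2 + nd + ax, 2 + ax]
    t = np.transpose(t, perm)
    out_sp = tuple(s * fa for s, fa in zip(spatial, f))
    outv = t.reshape((B, cout) + out_sp) + bv.reshape((1, cout) + (1,) * nd)
    if not grad_enabled():
        return Tensor(outv)

    def vjp(g: np.ndarray):
        db = g.sum(axis=(0,) + tuple(range(2, 2 + nd)))
        gb = g.reshape(
            (B, cout) + tuple(v for s, fa in zip(spatial, f) for v in (s, fa))
        )
        inv = [0, 1] + [2 + 2 * ax + 1 for ax in range(nd)] + [2 + 2 * ax for ax in range(nd)]
        gb = np.transpose(gb, inv)  # (B, cout, f0, f1.., s0, s1..)
        gb = gb.reshape(B, cout, int(np.prod(f)), n)
        dw = np.einsum("bofn,bcn->ocf", gb, xf, optimize=True).reshape(wv.shape)
        dx = np.einsum("ocf,bofn->bcn", wf, gb, optimize=True).reshape(xv.shape)
        return dx, dw, db

    return Tensor(outv, (x, w, b), vjp)


def max_pool(x: Tensor, factors: tuple[int, ...]) -> Tensor:
    """Max pooling by integer ``factors`` per spatial axis (1 = no pooling)."""
    xv = x.value
    B, c = xv.shape[:2]
    spatial = xv.shape[2:]
    nd = len(spatial)
    f = tuple(factors)
    for s, fa in zip(spatial, f):
        if s % fa != 0:
            raise ValueError(
                f"spatial shape {spatial} not divisible by pooling factors {f}"
            )
    out_sp = tuple(s // fa for s, fa in zip(spatial, f))
    shp = (B, c) + tuple(v for o, fa in zip(out_sp, f) for v in (o, fa))
    perm = [0, 1] + [2 + 2 * ax for ax in range(nd)] + [3 + 2 * ax for ax in range(nd)]
    blocks = np.transpose(xv.reshape(shp), perm).reshape(
        (B, c) + out_sp + (int(np.prod(f)),)
    )
    amax = blocks.argmax(axis=-1)
    outv = np.take_along_axis(blocks, amax[..., None], axis=-1)[..., 0]
    if not grad_enabled():
        return Tensor(outv)

    def vjp(g: np.ndarray):
        gb = np.zeros((B, c) + out_sp + (int(np.prod(f)),), dtype=np.float32)
        np.put_along_axis(gb, amax[..., None], g[..., None], axis=-1)
        gb = gb.reshape((B, c) + out_sp + f)
        inv = [0, 1]
        for ax in range(nd):
            inv += [2 + ax, 2 + nd + ax]
        gb = np.transpose(gb, inv).reshape(xv.shape)
        return (gb,)

    return Tensor(outv, (x,), vjp)


# ---------------------------------------------------------------------------
# pointwise / shape ops
# ---------------------------------------------------------------------------

def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    xv = x.value
    neg = xv < 0
    outv = np.where(neg, alpha * np.expm1(xv), xv)
    if not grad_enabled():
        return Tensor(outv)

    def vjp(g):
        return (np.where(neg, outv + alpha, 1.0).astype(np.float32) * g,)

    return Tensor(outv, (x,), vjp)


def relu(x: Tensor) -> Tensor:
    outv = np.maximum(x.value, 0.0)
    if not grad_enabled():
        return Tensor(outv)

    def vjp(g):
        return ((x.value > 0).astype(np.float32) * g,)

    return Tensor(outv, (x,), vjp)


def sigmoid(x: Tensor) -> Tensor:
    outv = 1.0 / (1.0 + np.exp(-x.value))
    if not grad_enabled():
        return Tensor(outv)

    def vjp(g):
        return (outv * (1.0 - outv) * g,)

    return Tensor(outv, (x,), vjp)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout: scales kept units by 1/(1-rate) at train time."""
    if not train or rate <= 0.0:
        return x
    keep = (rng.random(x.value.shape) >= rate).astype(np.float32) / (1.0 - rate)
    outv = x.value * keep
    if not grad_enabled():
        return Tensor(outv)

    def vjp(g):
        return (g * keep,)

    return Tensor(outv, (x,), vjp)


def dense(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x: (B, Cin), w: (Cout, Cin), b: (Cout,)."""
    outv = x.value @ w.value.T + b.value
    if not grad_enabled():
        return Tensor(outv)

    def vjp(g):
        return (g @ w.value, g.T @ x.value, g.sum(axis=0))

    return Tensor(outv, (x, w, b), vjp)


def concat(xs: Sequence[Tensor], axis: int = 1) -> Tensor:
    outv = np.concatenate([t.value for t in xs], axis=axis)
    if not grad_enabled():
        return Tensor(outv)
    sizes = [t.value.shape[axis] for t in xs]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        return tuple(
            np.take(g, range(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(xs))
        )

    return Tensor(outv, tuple(xs), vjp)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    outv = a.value + b.value
    if not grad_enabled():
        return Tensor(outv)

    def vjp(g):
        return _unbroadcast(g, a.value.shape), _unbroadcast(g, b.value.shape)

    return Tensor(outv, (a, b), vjp)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    outv = a.value * b.value
    if not grad_enabled():
        return Tensor(outv)

    def vjp(g):
        return (
            _unbroadcast(g * b.value, a.value.shape),
            _unbroadcast(g * a.value, b.value.shape),
        )

    return Tensor(outv, (a, b), vjp)


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    outv = x.value.reshape(shape)
    if not grad_enabled():
        return Tensor(outv)

    def vjp(g):
        return (g.reshape(x.value.shape),)

    return Tensor(outv, (x,), vjp)


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, *spatial) -> (B, C): the squeeze step of an SE block."""
    spatial_axes = tuple(range(2, x.value.ndim))
    n = int(np.prod(x.value.shape[2:]))
    outv = x.value.mean(axis=spatial_axes)
    if not grad_enabled():
        return Tensor(outv)

    def vjp(g):
        return (
            np.broadcast_to(
                g.reshape(g.shape + (1,) * len(spatial_axes)), x.value.shape
            ).astype(np.float32)
            / n,
        )

    return Tensor(outv, (x,), vjp)


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running: dict,
    train: bool,
    momentum: float = 0.9,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation over batch + spatial axes.

    ``running`` holds the non-trainable ``mean``/``var`` statistics (excluded
    from parameter counting).
    """
    xv = x.value
    axes = (0,) + tuple(range(2, xv.ndim))
    cshape = (1, xv.shape[1]) + (1,) * (xv.ndim - 2)
    if train:
        mean = xv.mean(axis=axes)
        var = xv.var(axis=axes)
        running["mean"] = momentum * running["mean"] + (1 - momentum) * mean
        running["var"] = momentum * running["var"] + (1 - momentum) * var
    else:
        mean, var = running["mean"], running["var"]
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xv - mean.reshape(cshape)) * inv.reshape(cshape)
    outv = gamma.value.reshape(cshape) * xhat + beta.value.reshape(cshape)
    if not grad_enabled():
        return Tensor(outv)
    m = xv.size // xv.shape[1]

    def vjp(g):
        dgamma = (g * xhat).sum(axis=axes)
        dbeta = g.sum(axis=axes)
        gx = g * gamma.value.reshape(cshape)
        if train:
            dx = (
                inv.reshape(cshape)
                / m
                * (
                    m * gx
                    - gx.sum(axis=axes).reshape(cshape)
                    - xhat * (gx * xhat).sum(axis=axes).reshape(cshape)
                )
            ).astype(np.float32)
        else:
            dx = gx * inv.reshape(cshape)
        return dx, dgamma, dbeta

    return Tensor(outv, (x, gamma, beta), vjp)


def bce_loss(pred: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy against a fixed 0/1 target array."""
    t = np.asarray(target, dtype=np.float32)
    p = np.clip(pred.value, eps, 1.0 - eps)
    outv = np.float32(-(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).mean())
    if not grad_enabled():
        return Tensor(outv)

    def vjp(g):
        inside = (pred.value > eps) & (pred.value < 1.0 - eps)
        dp = np.where(inside, (p - t) / (p * (1.0 - p)), 0.0) / p.size
        return (dp.astype(np.float32) * g,)

    return Tensor(outv, (pred,), vjp)


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------

class SGD:
    """Stochastic gradient descent with classical momentum, no decay.

    Update: ``v <- momentum * v - lr * grad;  p <- p + v``.
    """

    def __init__(self, params: Sequence[Tensor], lr: float = 0.002, momentum: float = 0.99):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v

    def zero_grad(self) -> None:
        zero_grad(self.params)
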