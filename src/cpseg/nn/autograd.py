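"""Reverse-mode autodiff on numpy arrays (float32).

The engine is a plain tape: every operation returns a new :class:`Tensor`
holding its inputs and a closure that accumulates gradients into them.
Only the operations required by the segmentation networks and loss
functions are implemented; all of them have exact analytic adjoints, which
the test suite verifies against central finite differences.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

_GRAD_ENABLED = True


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


@contextlib.contextmanager
def no_grad():
    """Disable tape construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (adjoint of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_diff = grad.ndim - len(shape)
    if ndim_diff > 0:
        grad = grad.sum(axis=tuple(range(ndim_diff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data, dtype=np.float32)
        # note: ascontiguousarray would promote 0-d scalars to shape (1,)
        self.data = arr if arr.flags.c_contiguous else np.ascontiguousarray(arr)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _result(data, parents: Sequence["Tensor"], backward: Callable[[np.ndarray], None]):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)

            def _bw():
                backward(out.grad)

            out._backward = _bw
        return out

    def _accum(self, g: np.ndarray):
        g = g.astype(np.float32, copy=False)
        if self.grad is None:
            self.grad = g.copy() if not g.flags.owndata else g
        else:
            self.grad += g

    # -- basic properties -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # the tape holds reference cycles (node -> closure -> node); break
        # them and drop intermediate buffers so memory is freed immediately
        for node in topo:
            if node._prev:
                node._backward = None
                node._prev = ()
                node.grad = None

    # -- elementwise algebra --------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float32))

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._result(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._result(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._result(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._result(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def pow(self, exponent: float):
        a = self
        e = float(exponent)
        out_data = a.data**e

        def bw(g):
            if a.requires_grad:
                a._accum(g * e * a.data ** (e - 1.0))

        return Tensor._result(out_data, (a,), bw)

    __pow__ = pow

    def log(self):
        a = self

        def bw(g):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._result(np.log(a.data), (a,), bw)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            if a.requires_grad:
                a._accum(g * out_data)

        return Tensor._result(out_data, (a,), bw)

    def clip(self, lo: float, hi: float):
        """Clamp with straight-through gradient inside [lo, hi]."""
        a = self
        mask = (a.data >= lo) & (a.data <= hi)

        def bw(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._result(np.clip(a.data, lo, hi), (a,), bw)

    def minimum(self, other: "Tensor"):
        """Elementwise minimum; ties route the gradient to `self`."""
        other = self._coerce(other)
        a, b = self, other
        take_a = a.data <= b.data

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * take_a, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * (~take_a), b.shape))

        return Tensor._result(np.minimum(a.data, b.data), (a, b), bw)

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).astype(np.float32))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).astype(np.float32))

        return Tensor._result(out_data, (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g):
            if a.requires_grad:
                a._accum(g.reshape(a.shape))

        return Tensor._result(a.data.reshape(shape), (a,), bw)

    def __getitem__(self, idx):
        a = self

        def bw(g):
            if a.requires_grad:
                ga = np.zeros_like(a.data)
                np.add.at(ga, idx, g)
                a._accum(ga)

        return Tensor._result(a.data[idx], (a,), bw)

# -- structural ops ------------------------------------------------------------


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    parts = list(tensors)
    sizes = [t.shape[axis] for t in parts]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, gpart in zip(parts, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(gpart)

    return Tensor._result(np.concatenate([t.data for t in parts], axis=axis), parts, bw)


def _shift_axis_replicate(a: np.ndarray, d: int, axis: int, out: np.ndarray):
    """out[i] = a[clip(i + d)] along `axis` (replicate border)."""
    h = a.shape[axis]

    def sl(s):
        idx = [slice(None)] * a.ndim
        idx[axis] = s
        return tuple(idx)

    if d == 0:
        out[...] = a
    elif d > 0:
        out[sl(slice(None, h - d))] = a[sl(slice(d, None))]
        out[sl(slice(h - d, None))] = a[sl(slice(h - 1, h))]
    else:
        out[sl(slice(-d, None))] = a[sl(slice(None, h + d))]
        out[sl(slice(None, -d))] = a[sl(slice(0, 1))]


def _shift_axis_adjoint(g: np.ndarray, d: int, axis: int, acc: np.ndarray):
    """Adjoint of _shift_axis_replicate: scatter-add g back into acc."""
    h = acc.shape[axis]

    def sl(s):
        idx = [slice(None)] * g.ndim
        idx[axis] = s
        return tuple(idx)

    if d == 0:
        acc += g
    elif d > 0:
        acc[sl(slice(d, None))] += g[sl(slice(None, h - d))]
        acc[sl(slice(h - 1, h))] += g[sl(slice(h - d, None))].sum(axis=axis, keepdims=True)
    else:
        acc[sl(slice(None, h + d))] += g[sl(slice(-d, None))]
        acc[sl(slice(0, 1))] += g[sl(slice(None, -d))].sum(axis=axis, keepdims=True)


def erode2d(x: Tensor, offsets: Sequence[tuple]) -> Tensor:
    """Grayscale erosion over the last two axes: min over shifted copies.

    Border handling is replicate, so a constant map is a fixed point. The
    forward pass is a running minimum (no offset stack is materialized);
    the backward pass recomputes the shifts and splits the gradient
    equally among tied minima (the subgradient of min).
    """
    rows, cols = x.ndim - 2, x.ndim - 1
    tmp = np.empty(x.shape, dtype=np.float32)
    sh = np.empty(x.shape, dtype=np.float32)
    out = np.full(x.shape, np.inf, dtype=np.float32)
    for di, dj in offsets:
        _shift_axis_replicate(x.data, di, rows, tmp)
        _shift_axis_replicate(tmp, dj, cols, sh)
        np.minimum(out, sh, out=out)

    def bw(g):
        if not x.requires_grad:
            return
        counts = np.zeros(x.shape, dtype=np.float32)
        t1 = np.empty(x.shape, dtype=np.float32)
        t2 = np.empty(x.shape, dtype=np.float32)
        for di, dj in offsets:
            _shift_axis_replicate(x.data, di, rows, t1)
            _shift_axis_replicate(t1, dj, cols, t2)
            counts += t2 == out
        gshare = g / counts
        gx = np.zeros_like(x.data)
        for di, dj in offsets:
            _shift_axis_replicate(x.data, di, rows, t1)
            _shift_axis_replicate(t1, dj, cols, t2)
            gm = np.where(t2 == out, gshare, 0.0).astype(np.float32)
            # adjoint of (shift rows by di then cols by dj): reverse order
            t1[...] = 0.0
            _shift_axis_adjoint(gm, dj, cols, t1)
            _shift_axis_adjoint(t1, di, rows, gx)
        x._accum(gx)

    return Tensor._result(out, (x,), bw)


# -- N-d convolution primitives -------------------------------------------------


def conv_nd(x: Tensor, w: Tensor, b: Tensor | None, pad: int) -> Tensor:
    """'Same'-style N-d convolution (correlation), stride 1.

    x: (N, Cin, *S); w: (Cout, Cin, *K) with odd kernel; pad = k // 2 keeps
    the spatial shape. Implemented as explicit im2col followed by one
    batched GEMM per sample, which on CPU beats windowed tensordot by a
    wide margin (the window view reshape is a cache-hostile copy).
    """
    import itertools

    nd = x.ndim - 2
    k = w.shape[2]
    n, cin = x.shape[:2]
    cout = w.shape[0]
    spatial = x.shape[2:]
    hw = int(np.prod(spatial))
    nk = k**nd
    offsets = list(itertools.product(range(k), repeat=nd))
    xp = np.pad(x.data, [(0, 0), (0, 0)] + [(pad, pad)] * nd)
    col = np.empty((n, cin * nk, hw), dtype=np.float32)
    colv = col.reshape((n, cin, nk) + spatial)
    for ki, offs in enumerate(offsets):
        sl = tuple(slice(o, o + s) for o, s in zip(offs, spatial))
        colv[:, :, ki] = xp[(slice(None), slice(None)) + sl]
    wmat = w.data.reshape(cout, cin * nk)
    out = np.matmul(wmat[None], col).reshape((n, cout) + spatial)
    if b is not None:
        out += b.data.reshape((1, -1) + (1,) * nd)

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        g2 = g.reshape(n, cout, hw)
        if w.requires_grad:
            gw = np.matmul(g2, col.transpose(0, 2, 1)).sum(axis=0)
            w._accum(gw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accum(g2.sum(axis=(0, 2)))
        if x.requires_grad:
            dcol = np.matmul(wmat.T[None], g2)  # (n, cin*nk, hw)
            dcolv = dcol.reshape((n, cin, nk) + spatial)
            dxp = np.zeros_like(xp)
            for ki, offs in enumerate(offsets):
                sl = tuple(slice(o, o + s) for o, s in zip(offs, spatial))
                dxp[(slice(None), slice(None)) + sl] += dcolv[:, :, ki]
            core = tuple(slice(pad, pad + s) for s in spatial)
            x._accum(dxp[(slice(None), slice(None)) + core])

    return Tensor._result(np.ascontiguousarray(out), parents, bw)


def zero_insert(x: Tensor, stride: int = 2) -> Tensor:
    """Upsample by inserting zeros: output spatial size = stride * input size.

    Followed by a 'same' convolution this realises a transposed convolution
    that exactly doubles each spatial dimension.
    """
    nd = x.ndim - 2
    out_shape = x.shape[:2] + tuple(s * stride for s in x.shape[2:])
    sl = (slice(None), slice(None)) + (slice(None, None, stride),) * nd
    out = np.zeros(out_shape, dtype=np.float32)
    out[sl] = x.data

    def bw(g):
        if x.requires_grad:
            x._accum(g[sl])

    return Tensor._result(out, (x,), bw)


def max_pool_nd(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling; spatial dims must divide `size`."""
    nd = x.ndim - 2
    spatial = x.shape[2:]
    if any(s % size for s in spatial):
        raise ValueError(f"spatial shape {spatial} not divisible by pool size {size}")
    newsp = tuple(s // size for s in spatial)
    shape = x.shape[:2] + tuple(v for s in newsp for v in (s, size))
    xr = x.data.reshape(shape)
    # move the window axes (3, 5, ...) to the end, flatten them
    win_axes = tuple(3 + 2 * i for i in range(nd))
    xr = np.moveaxis(xr, win_axes, tuple(range(-nd, 0)))
    flat = xr.reshape(x.shape[:2] + newsp + (size**nd,))
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def bw(g):
        if not x.requires_grad:
            return
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, arg[..., None], g[..., None], axis=-1)
        gr = gflat.reshape(x.shape[:2] + newsp + (size,) * nd)
        gr = np.moveaxis(gr, tuple(range(-nd, 0)), win_axes)
        x._accum(np.ascontiguousarray(gr.reshape(x.shape)))

    return Tensor._result(np.ascontiguousarray(out), (x,), bw)


def elu_op(x: Tensor, alpha: float = 1.0) -> Tensor:
    pos = x.data > 0
    out = np.where(pos, x.data, alpha * (np.exp(np.minimum(x.data, 0.0)) - 1.0)).astype(np.float32)

    def bw(g):
        if x.requires_grad:
            x._accum(g * np.where(pos, 1.0, out + alpha).astype(np.float32))

    return Tensor._result(out, (x,), bw)


def softmax_op(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        if x.requires_grad:
            dot = (g * out).sum(axis=axis, keepdims=True)
            x._accum(out * (g - dot))

    return Tensor._result(out, (x,), bw)


def batch_norm_op(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over (N, *spatial) per channel; updates running stats in place."""
    nd = x.ndim - 2
    axes = (0,) + tuple(range(2, x.ndim))
    shape = (1, -1) + (1,) * nd
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(shape)) * invstd.reshape(shape)
    out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)
    m = float(np.prod([x.shape[a] for a in axes]))

    def bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            gs = g * gamma.data.reshape(shape)
            if training:
                gx = (
                    gs
                    - gs.mean(axis=axes, keepdims=True)
                    - xhat * (gs * xhat).mean(axis=axes, keepdims=True)
                ) * invstd.reshape(shape)
            else:
                gx = gs * invstd.reshape(shape)
            x._accum(gx.astype(np.float32))

    _ = m  # batch-size factor folded into the means above
    return Tensor._result(out.astype(np.float32), (x, gamma, beta), bw)
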