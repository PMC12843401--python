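"""Reverse-mode automatic differentiation over numpy arrays.

A minimal tape-based tensor engine: each :class:`Tensor` wraps an
``np.ndarray`` and records the operation that produced it, so that
``Tensor.backward`` can propagate gradients through arbitrary compositions
of the primitives defined here. Only what the segmentation network needs is
implemented — elementwise arithmetic with broadcasting, matmul, reductions,
shape manipulation, the activations used by the model, grouped 2-D
convolution (im2col) and bilinear resampling.

Gradient correctness of every primitive is established by central-difference
checks in the test-suite rather than trusted by construction.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "concatenate",
    "stack",
    "conv2d",
    "upsample_bilinear",
    "softmax",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float64 if np.asarray(data).dtype.kind != "f" else None)
        if self.data.dtype != np.float64:
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out._parents = ()
        out._backward = None
        out.requires_grad = False
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic protocol ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -- autograd ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=np.float64)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS post-order (graphs can be deep: 12 encoder layers)
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            pending = [p for p in unvisited if p._parents]
            if pending:
                stack.extend(pending)
            else:
                for p in unvisited:
                    seen.add(id(p))
                    topo.append(p)
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None or node._backward is None:
                if g is not None and node._backward is None:
                    node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if p._parents and p._backward is not None:
                    acc = grads.get(id(p))
                    grads[id(p)] = pg if acc is None else acc + pg
                else:
                    p.grad = pg if p.grad is None else p.grad + pg

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        data = a.data + b.data

        def bwd(g):
            return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

        return Tensor._make(data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        data = a.data - b.data

        def bwd(g):
            return _unbroadcast(g, a.data.shape), _unbroadcast(-g, b.data.shape)

        return Tensor._make(data, (a, b), bwd)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        data = a.data * b.data

        def bwd(g):
            return (
                _unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape),
            )

        return Tensor._make(data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        data = a.data / b.data

        def bwd(g):
            return (
                _unbroadcast(g / b.data, a.data.shape),
                _unbroadcast(-g * a.data / (b.data**2), b.data.shape),
            )

        return Tensor._make(data, (a, b), bwd)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, exponent: float):
        a = self
        data = a.data**exponent

        def bwd(g):
            return (g * exponent * a.data ** (exponent - 1),)

        return Tensor._make(data, (a,), bwd)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        data = np.matmul(a.data, b.data)

        def bwd(g):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

        return Tensor._make(data, (a, b), bwd)

    # -- elementwise functions -----------------------------------------------
    def exp(self):
        a = self
        data = np.exp(a.data)
        return Tensor._make(data, (a,), lambda g: (g * data,))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: (g / a.data,))

    def sqrt(self):
        a = self
        data = np.sqrt(a.data)
        return Tensor._make(data, (a,), lambda g: (g * 0.5 / data,))

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: (g * mask,))

    def relu6(self):
        a = self
        mask = (a.data > 0) & (a.data < 6.0)
        return Tensor._make(np.clip(a.data, 0.0, 6.0), (a,), lambda g: (g * mask,))

    def sigmoid(self):
        a = self
        data = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(data, (a,), lambda g: (g * data * (1.0 - data),))

    def gelu(self):
        # exact Gaussian error linear unit: x * Phi(x)
        from scipy.special import erf

        a = self
        cdf = 0.5 * (1.0 + erf(a.data / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * a.data**2) / np.sqrt(2.0 * np.pi)
        data = a.data * cdf
        return Tensor._make(data, (a,), lambda g: (g * (cdf + a.data * pdf),))

    def clip_min(self, lo: float):
        a = self
        mask = a.data > lo
        return Tensor._make(np.maximum(a.data, lo), (a,), lambda g: (g * mask,))

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        data = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis if isinstance(axis, tuple) else (axis,))
            return (np.broadcast_to(g, a.data.shape).copy(),)

        return Tensor._make(data, (a,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims=False):
        a = self
        data = a.data.max(axis=axis, keepdims=keepdims)
        # route gradient to the first maximiser along the axis
        idx = a.data.argmax(axis=axis)

        def bwd(g):
            g = np.asarray(g)
            if keepdims:
                g = np.squeeze(g, axis=axis)
            out = np.zeros_like(a.data)
            np.put_along_axis(
                out, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis
            )
            return (out,)

        return Tensor._make(data, (a,), bwd)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        data = a.data.reshape(shape)
        return Tensor._make(data, (a,), lambda g: (g.reshape(a.data.shape),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)
        data = a.data.transpose(axes)
        return Tensor._make(data, (a,), lambda g: (g.transpose(inv),))

    def swapaxes(self, ax1, ax2):
        axes = list(range(self.data.ndim))
        axes[ax1], axes[ax2] = axes[ax2], axes[ax1]
        return self.transpose(*axes)

    def __getitem__(self, key):
        a = self
        data = a.data[key]

        def bwd(g):
            out = np.zeros_like(a.data)
            np.add.at(out, key, g)
            return (out,)

        return Tensor._make(data, (a,), bwd)

    def pad2d(self, pad: int):
        """Zero-pad the trailing two axes by ``pad`` on every side."""
        if pad == 0:
            return self
        a = self
        width = [(0, 0)] * (a.data.ndim - 2) + [(pad, pad), (pad, pad)]
        data = np.pad(a.data, width)
        sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
        return Tensor._make(data, (a,), lambda g: (g[sl],))


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(data, tuple(tensors), bwd)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor._make(data, tuple(tensors), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically-stable softmax; the shift is a constant w.r.t. the graph."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# grouped 2-D convolution (im2col)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(B, C, H, W) -> (B, C, kh, kw, Ho, Wo) view."""
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # B,C,Ho',Wo',kh,kw
    win = win[:, :, ::stride, ::stride]
    return np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3))


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D convolution, ``x``: (B, Cin, H, W), ``weight``: (Cout, Cin/g, kh, kw)."""
    xp = x.pad2d(padding)
    B, Cin, H, W = xp.data.shape
    Cout, Cg, kh, kw = weight.data.shape
    if Cin != Cg * groups:
        raise ValueError(
            f"conv2d channel mismatch: input has {Cin} channels, "
            f"weight expects {Cg * groups} (groups={groups})"
        )
    Ho = (H - kh) // stride + 1
    Wo = (W - kw) // stride + 1
    cols = _im2col(xp.data, kh, kw, stride)  # B,Cin,kh,kw,Ho,Wo
    cols_g = cols.reshape(B, groups, Cg * kh * kw, Ho * Wo)
    w_g = weight.data.reshape(groups, Cout // groups, Cg * kh * kw)
    out = np.matmul(w_g[None], cols_g)  # (B, g, Cout/g, Ho*Wo)
    out = out.reshape(B, Cout, Ho, Wo)
    if bias is not None:
        out = out + bias.data.reshape(1, Cout, 1, 1)

    parents = (xp, weight) + ((bias,) if bias is not None else ())

    def bwd(g):
        g4 = g.reshape(B, groups, Cout // groups, Ho * Wo)
        gw = np.matmul(g4, cols_g.swapaxes(-1, -2)).sum(axis=0)
        gw = gw.reshape(weight.data.shape)
        gcols = np.matmul(w_g.swapaxes(-1, -2)[None], g4)
        gcols = gcols.reshape(B, Cin, kh, kw, Ho, Wo)
        gx = np.zeros((B, Cin, H, W))
        for i in range(kh):
            hi = i + stride * Ho
            for j in range(kw):
                wj = j + stride * Wo
                gx[:, :, i:hi:stride, j:wj:stride] += gcols[:, :, i, j]
        grads = [gx, gw]
        if bias is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return tuple(grads)

    return Tensor._make(out, parents, bwd)


# ---------------------------------------------------------------------------
# bilinear resampling (align_corners=False)
# ---------------------------------------------------------------------------

def _bilinear_weights(n_in: int, n_out: int):
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(np.intp)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    return lo, hi, frac


def upsample_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of (B, C, H, W) to (B, C, out_h, out_w)."""
    B, C, H, W = x.data.shape
    rlo, rhi, rf = _bilinear_weights(H, out_h)
    clo, chi, cf = _bilinear_weights(W, out_w)
    rf = rf[:, None]
    cf = cf[None, :]

    d = x.data
    top = d[:, :, rlo][:, :, :, clo] * (1 - cf) + d[:, :, rlo][:, :, :, chi] * cf
    bot = d[:, :, rhi][:, :, :, clo] * (1 - cf) + d[:, :, rhi][:, :, :, chi] * cf
    out = top * (1 - rf) + bot * rf

    def bwd(g):
        gx = np.zeros_like(d)
        for rw, ridx in ((1 - rf, rlo), (rf, rhi)):
            for cw, cidx in ((1 - cf, clo), (cf, chi)):
                contrib = g * rw * cw
                # scatter-add over duplicated indices
                np.add.at(gx, (slice(None), slice(None), ridx[:, None], cidx[None, :]), contrib)
        return (gx,)

    return Tensor._make(out, (x,), bwd)
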