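"""A small reverse-mode automatic-differentiation engine over NumPy arrays.

The networks in this package are small enough (60x60 grayscale inputs,
tens of thousands to a few million parameters) that a dedicated tensor
engine with a dynamic tape is both sufficient and fully deterministic on a
single CPU.  ``Tensor`` wraps an ``ndarray``, records the operations that
produced it, and ``backward()`` walks the tape in reverse topological order
accumulating gradients.  Broadcasting follows NumPy semantics; gradients of
broadcast operands are summed back to the operand's shape.

Only the operations the architectures need are provided: elementwise
arithmetic, matmul (with batch broadcasting), reductions, reshape /
transpose / slicing, relu / sigmoid / exp / log / sqrt, a numerically
stable softmax, 2-D convolution via im2col, and max pooling.  Convolution
and pooling carry hand-written backward rules; everything else composes.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        # float32 and float64 are preserved (networks train in float32);
        # anything else promotes to float64
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor._make(self.data + other.data, (self, other), None)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor._make(self.data * other.data, (self, other), None)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor._make(self.data ** p, (self,), None)

        def backward(g):
            return (g * p * self.data ** (p - 1.0),)

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor._make(np.matmul(self.data, other.data), (self, other), None)

        def backward(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        out._backward = backward
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor._make(self.data.reshape(shape), (self,), None)
        out._backward = lambda g: (g.reshape(self.shape),)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor._make(self.data.transpose(axes), (self,), None)
        out._backward = lambda g: (g.transpose(inv),)
        return out

    def __getitem__(self, idx):
        out = Tensor._make(self.data[idx], (self,), None)

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = backward
        return out

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor._make(self.data * mask, (self,), None)
        out._backward = lambda g: (g * mask,)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor._make(s, (self,), None)
        out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor._make(e, (self,), None)
        out._backward = lambda g: (g * e,)
        return out

    def log(self):
        out = Tensor._make(np.log(self.data), (self,), None)
        out._backward = lambda g: (g / self.data,)
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = Tensor._make(r, (self,), None)
        out._backward = lambda g: (g * 0.5 / r,)
        return out

    # -- backward pass --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep nets overflow the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    def zero_grad(self):
        self.grad = None


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- composed / custom ops ----------------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int):
    n, c, h, w = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    sn, sc, sh, sw = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, ho, wo),
        strides=(sn, sc, sh, sw, sh * stride, sw * stride),
        writeable=False,
    )
    return cols.reshape(n, c * kh * kw, ho * wo), ho, wo


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, ho: int, wo: int):
    n, c, h, w = x_shape
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    out = np.zeros(x_shape, dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += cols[
                :, :, i, j
            ]
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout, via im2col.

    ``x``: (N, C, H, W); ``w``: (F, C, kh, kw); ``b``: (F,) or None.
    """
    f, c, kh, kw = w.shape
    xp = x.data if pad == 0 else np.pad(
        x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))
    )
    cols, ho, wo = _im2col(xp, kh, kw, stride)  # (N, C*kh*kw, L)
    wmat = w.data.reshape(f, c * kh * kw)
    out_data = np.matmul(wmat, cols).reshape(x.shape[0], f, ho, wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, f, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor._make(out_data, parents, None)
    cols_saved = np.ascontiguousarray(cols)

    def backward(g):
        gmat = g.reshape(g.shape[0], f, ho * wo)  # (N, F, L)
        gw = np.tensordot(gmat, cols_saved, axes=([0, 2], [0, 2])).reshape(w.shape)
        gcols = np.matmul(wmat.T[None], gmat)  # (N, C*kh*kw, L)
        gxp = _col2im(gcols, xp.shape, kh, kw, stride, ho, wo)
        gx = gxp if pad == 0 else gxp[:, :, pad:-pad, pad:-pad]
        if b is None:
            return (gx, gw)
        return (gx, gw, g.sum(axis=(0, 2, 3)))

    out._backward = backward
    return out


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k x k max pooling; trailing rows/cols beyond a multiple
    of ``k`` are dropped (floor behaviour)."""
    n, c, h, w = x.shape
    ho, wo = h // k, w // k
    xc = x.data[:, :, : ho * k, : wo * k]
    blocks = xc.reshape(n, c, ho, k, wo, k)
    out_data = blocks.max(axis=(3, 5))
    mask = blocks == out_data[:, :, :, None, :, None]
    out = Tensor._make(out_data, (x,), None)

    def backward(g):
        gb = mask * g[:, :, :, None, :, None]
        gx = np.zeros_like(x.data)
        gx[:, :, : ho * k, : wo * k] = gb.reshape(n, c, ho * k, wo * k)
        return (gx,)

    out._backward = backward
    return out


def einsum(spec: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum with analytic backward.

    Requires every index of each operand to appear in the output or in the
    other operand (no diagonals), which holds for the capsule-routing
    contractions this engine needs; the gradient of each operand is then
    itself a single einsum.
    """
    a, b = _as_tensor(a), _as_tensor(b)
    ins, out_spec = spec.replace(" ", "").split("->")
    spec_a, spec_b = ins.split(",")
    for sub, other in ((spec_a, spec_b), (spec_b, spec_a)):
        if not set(sub) <= set(out_spec) | set(other):
            raise ValueError(f"unsupported einsum for autodiff: {spec!r}")
    out = Tensor._make(np.einsum(spec, a.data, b.data), (a, b), None)

    def backward(g):
        ga = np.einsum(f"{out_spec},{spec_b}->{spec_a}", g, b.data)
        gb = np.einsum(f"{out_spec},{spec_a}->{spec_b}", g, a.data)
        return (ga, gb)

    out._backward = backward
    return out


def batchnorm_train(x: Tensor, gamma: Tensor, beta: Tensor,
                    eps: float = 1e-5) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused batch normalization over batch (and spatial) axes.

    ``x`` is (N, C) or (N, C, H, W); gamma/beta are (C,).  Returns the
    normalized output plus the batch mean/var as plain arrays (for running-
    statistics bookkeeping).  The backward pass uses the standard closed
    form instead of composing elementwise ops, which matters for deep
    stacks of small convolutions.
    """
    spatial = x.ndim == 4
    axes = (0, 2, 3) if spatial else (0,)
    shape = (1, -1, 1, 1) if spatial else (1, -1)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gdat = gamma.data.reshape(shape)
    out = Tensor._make(xhat * gdat + beta.data.reshape(shape), (x, gamma, beta), None)
    n = x.data.size // x.data.shape[1]

    def backward(g):
        ggamma = (g * xhat).sum(axis=axes)
        gbeta = g.sum(axis=axes)
        gxhat = g * gdat
        s1 = gxhat.sum(axis=axes, keepdims=True)
        s2 = (gxhat * xhat).sum(axis=axes, keepdims=True)
        gx = (inv / n) * (n * gxhat - s1 - xhat * s2)
        return (gx, ggamma, gbeta)

    out._backward = backward
    return out, mu.ravel(), var.ravel()


def stack_params(*tensors: Tensor) -> list[Tensor]:
    return [t for t in tensors if t is not None]
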