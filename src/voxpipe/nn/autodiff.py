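"""A compact reverse-mode automatic-differentiation core on numpy arrays.

Provides exactly the operations the volumetric networks in this package
need: elementwise arithmetic with broadcasting, matmul, 3-D convolution via
im2col, channel concatenation, 2x average-pool downsampling and trilinear
upsampling, reductions, and the usual nonlinearities.  Tensors record the
operations that produced them; ``Tensor.backward()`` walks the graph in
reverse topological order accumulating gradients into leaf ``Variable``s.

Arrays are float32 throughout; the convention for feature maps is
``(batch, channels, x, y, z)``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph bookkeeping ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in node._backward(node.grad):
                if pgrad is None:
                    continue
                pgrad = _unbroadcast(pgrad, parent.data.shape)
                if parent.grad is None:
                    parent.grad = pgrad.astype(DTYPE)
                else:
                    parent.grad = parent.grad + pgrad.astype(DTYPE)

    # -- operator sugar ------------------------------------------------------

    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), as_tensor(-1.0)))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, as_tensor(-1.0)))

    def __truediv__(self, other):
        return mul(self, power(as_tensor(other), -1.0))

    def __neg__(self):
        return mul(self, as_tensor(-1.0))

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))


class Variable(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient over the axes that numpy broadcasting expanded."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _op(data, parents, backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=parents if req else (),
                  backward=backward if req else None)


# ---------------------------------------------------------------------------
# elementwise and linear algebra
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    return _op(a.data + b.data, (a, b), lambda g: [(a, g), (b, g)])


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _op(a.data * b.data, (a, b),
               lambda g: [(a, g * b.data), (b, g * a.data)])


def power(a: Tensor, exponent: float) -> Tensor:
    out = a.data ** exponent
    return _op(out, (a,),
               lambda g: [(a, g * exponent * a.data ** (exponent - 1.0))])


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return _op(a.data @ b.data, (a, b),
               lambda g: [(a, g @ np.swapaxes(b.data, -1, -2)),
                          (b, np.swapaxes(a.data, -1, -2) @ g)])


def exp(a: Tensor) -> Tensor:
    out = np.exp(a.data)
    return _op(out, (a,), lambda g: [(a, g * out)])


def log(a: Tensor, eps: float = 0.0) -> Tensor:
    return _op(np.log(a.data + eps), (a,), lambda g: [(a, g / (a.data + eps))])


def sqrt(a: Tensor) -> Tensor:
    out = np.sqrt(a.data)
    return _op(out, (a,), lambda g: [(a, g * 0.5 / np.maximum(out, 1e-12))])


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    return _op(a.data * mask, (a,), lambda g: [(a, g * mask)])


def leaky_relu(a: Tensor, alpha: float = 0.01) -> Tensor:
    slope = np.where(a.data > 0, 1.0, alpha).astype(DTYPE)
    return _op(a.data * slope, (a,), lambda g: [(a, g * slope)])


def sigmoid(a: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-a.data))
    return _op(out, (a,), lambda g: [(a, g * out * (1.0 - out))])


def tanh(a: Tensor) -> Tensor:
    out = np.tanh(a.data)
    return _op(out, (a,), lambda g: [(a, g * (1.0 - out * out))])


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return [(a, np.broadcast_to(g, a.data.shape))]
        gg = g if keepdims else np.expand_dims(g, axis)
        return [(a, np.broadcast_to(gg, a.data.shape))]

    return _op(out, (a,), backward)


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in np.atleast_1d(axis)])
    return mul(sum_(a, axis=axis, keepdims=keepdims), as_tensor(1.0 / float(n)))


def reshape(a: Tensor, shape) -> Tensor:
    orig = a.data.shape
    return _op(a.data.reshape(shape), (a,), lambda g: [(a, g.reshape(orig))])


def transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)
    return _op(a.data.transpose(axes), (a,), lambda g: [(a, g.transpose(inv))])


def concat(tensors, axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return list(zip(tensors, parts))

    return _op(np.concatenate([t.data for t in tensors], axis=axis),
               tuple(tensors), backward)


def softmax(a: Tensor, axis: int = 1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return [(a, out * (g - dot))]

    return _op(out, (a,), backward)


# ---------------------------------------------------------------------------
# spatial operations on (batch, channels, x, y, z) feature maps
# ---------------------------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1, zero-padded ('same') 3-D convolution via im2col.

    x: (N, C, X, Y, Z); w: (Cout, C, k, k, k); b: (Cout,).
    """
    n, c, dx, dy, dz = x.data.shape
    cout, cin, k1, k2, k3 = w.data.shape
    if cin != c:
        raise ValueError(f"conv3d channel mismatch: input {c}, weight {cin}")
    pads = (k1 // 2, k2 // 2, k3 // 2)
    xp = np.pad(x.data, ((0, 0), (0, 0)) + tuple((p, p) for p in pads))
    # columns: (N, X, Y, Z, C, k1, k2, k3)
    cols = np.lib.stride_tricks.sliding_window_view(xp, (k1, k2, k3), axis=(2, 3, 4))
    cols = cols.transpose(0, 2, 3, 4, 1, 5, 6, 7)
    cols_mat = cols.reshape(n, dx * dy * dz, c * k1 * k2 * k3)
    w_mat = w.data.reshape(cout, c * k1 * k2 * k3)
    out = cols_mat @ w_mat.T  # (N, XYZ, Cout)
    if b is not None:
        out = out + b.data[np.newaxis, np.newaxis, :]
    out = out.transpose(0, 2, 1).reshape(n, cout, dx, dy, dz)

    def backward(g):
        g_mat = g.reshape(n, cout, dx * dy * dz).transpose(0, 2, 1)  # (N, XYZ, Cout)
        dw = np.einsum("npo,npk->ok", g_mat, cols_mat).reshape(w.data.shape)
        grads = [(w, dw)]
        if b is not None:
            grads.append((b, g_mat.sum(axis=(0, 1))))
        dcols = g_mat @ w_mat  # (N, XYZ, C*k^3)
        dcols = dcols.reshape(n, dx, dy, dz, c, k1, k2, k3)
        dxp = np.zeros_like(xp)
        for a1 in range(k1):
            for a2 in range(k2):
                for a3 in range(k3):
                    dxp[:, :, a1:a1 + dx, a2:a2 + dy, a3:a3 + dz] += \
                        dcols[:, :, :, :, :, a1, a2, a3].transpose(0, 4, 1, 2, 3)
        sl = tuple(slice(p, p + d) for p, d in zip(pads, (dx, dy, dz)))
        grads.append((x, dxp[:, :, sl[0], sl[1], sl[2]]))
        return grads

    parents = (x, w) if b is None else (x, w, b)
    return _op(out, parents, backward)


def avg_pool2(x: Tensor) -> Tensor:
    """2x average-pool downsampling of each spatial axis."""
    n, c, dx, dy, dz = x.data.shape
    if dx % 2 or dy % 2 or dz % 2:
        raise ValueError(f"avg_pool2 needs even spatial dims, got {(dx, dy, dz)}")
    r = x.data.reshape(n, c, dx // 2, 2, dy // 2, 2, dz // 2, 2)
    out = r.mean(axis=(3, 5, 7))

    def backward(g):
        gg = g[:, :, :, None, :, None, :, None] / 8.0
        gx = np.broadcast_to(gg, (n, c, dx // 2, 2, dy // 2, 2, dz // 2, 2))
        return [(x, gx.reshape(n, c, dx, dy, dz))]

    return _op(out, (x,), backward)


def _linear_weights(size_out: int, size_in: int) -> np.ndarray:
    """Sparse interpolation matrix for 2x (align_corners=False) upsampling."""
    w = np.zeros((size_out, size_in), dtype=DTYPE)
    for i in range(size_out):
        src = (i + 0.5) / 2.0 - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), size_in - 1)
        hi_c = min(max(lo + 1, 0), size_in - 1)
        w[i, lo_c] += 1.0 - frac
        w[i, hi_c] += frac
    return w


def upsample2_linear(x: Tensor) -> Tensor:
    """2x trilinear upsampling (separable: one linear map per axis)."""
    n, c, dx, dy, dz = x.data.shape
    mats = [_linear_weights(2 * d, d) for d in (dx, dy, dz)]
    out = np.einsum("ai,ncijk->ncajk", mats[0], x.data)
    out = np.einsum("bj,ncajk->ncabk", mats[1], out)
    out = np.einsum("ck,nxabk->nxabc", mats[2], out)

    def backward(g):
        gx = np.einsum("ck,nxabc->nxabk", mats[2], g)
        gx = np.einsum("bj,ncabk->ncajk", mats[1], gx)
        gx = np.einsum("ai,ncajk->ncijk", mats[0], gx)
        return [(x, gx)]

    return _op(out, (x,), backward)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize each (sample, channel) feature map over its spatial axes.

    Batch-independent, so behaviour is identical at any batch size; gamma
    and beta are per-channel scale and shift of shape (1, C, 1, 1, 1).
    """
    axes = (2, 3, 4)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = gamma.data * xhat + beta.data
    m = float(np.prod([x.data.shape[a] for a in axes]))

    def backward(g):
        dbeta = g.sum(axis=(0, 2, 3, 4), keepdims=True)
        dgamma = (g * xhat).sum(axis=(0, 2, 3, 4), keepdims=True)
        gh = g * gamma.data
        term = gh - gh.mean(axis=axes, keepdims=True) \
            - xhat * (gh * xhat).mean(axis=axes, keepdims=True)
        return [(x, term * inv), (gamma, dgamma), (beta, dbeta)]

    return _op(out, (x, gamma, beta), backward)
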