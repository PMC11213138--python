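"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; calling :meth:`Tensor.backward` on a scalar result propagates gradients to
every tensor created with ``requires_grad=True``. The op set is deliberately
small — exactly what a convolution/attention regression network and simplex
gradient ascent need — and every op's backward pass is validated against
finite differences in the test suite.

Gradients accumulate into ``.grad``; call :func:`zero_grads` (or the
optimizer's ``zero_grad``) between backward passes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "softmax", "relu", "matmul", "pad1d", "unfold1d",
           "maxpool1d", "conv1d", "clipped_exp", "layer_norm", "dropout", "zero_grads",
           "no_grad_params", "set_default_dtype", "default_dtype"]

#: dtype of all tensor data; float32 is the working default, float64 is used
#: by the finite-difference gradient checks
_DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global _DTYPE
    _DTYPE = np.dtype(dtype).type


def default_dtype():
    return _DTYPE


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_owned")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self._grad_owned = False
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------ #
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        # first contribution adopts the array without copying; a second
        # contribution forces a private buffer before accumulating in place
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        else:
            if not self._grad_owned:
                self.grad = self.grad + g
                self._grad_owned = True
            else:
                self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self._accum(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------- #
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.data.shape))

        out._backward = bw
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))
        out._backward = lambda g: self._accum(
            g * exponent * self.data ** (exponent - 1))
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    # -- reductions / shape --------------------------------------------- #
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(*inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))
        basic = isinstance(idx, (int, slice)) or (
            isinstance(idx, tuple)
            and all(isinstance(i, (int, slice)) for i in idx))

        def bw(g):
            full = np.zeros_like(self.data)
            if basic:           # each output element maps to one input slot
                full[idx] = g
            else:
                np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


# ---------------------------------------------------------------------- #
def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product with numpy batch broadcasting on leading axes."""
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.data.shape))

    out._backward = bw
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))
    out._backward = lambda g: x._accum(g * (x.data > 0))
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, parents=(x,))

    def bw(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accum((g - dot) * s)

    out._backward = bw
    return out


def pad1d(x: Tensor, left: int, right: int) -> Tensor:
    """Zero-pad along axis 1 of a (batch, length, channels) tensor."""
    out = Tensor(np.pad(x.data, ((0, 0), (left, right), (0, 0))), parents=(x,))
    L = x.data.shape[1]
    out._backward = lambda g: x._accum(g[:, left:left + L, :])
    return out


def unfold1d(x: Tensor, width: int) -> Tensor:
    """Sliding windows along axis 1: (B, L, C) -> (B, L-width+1, width*C)."""
    B, L, C = x.data.shape
    Lo = L - width + 1
    win = np.lib.stride_tricks.sliding_window_view(x.data, width, axis=1)
    # sliding_window_view appends the window axis: (B, Lo, C, width)
    out_data = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, Lo, width * C)
    out = Tensor(out_data, parents=(x,))

    def bw(g):
        gw = g.reshape(B, Lo, width, C)
        gx = np.zeros_like(x.data)
        for j in range(width):
            gx[:, j:j + Lo, :] += gw[:, :, j, :]
        x._accum(gx)

    out._backward = bw
    return out


def maxpool1d(x: Tensor, pool: int) -> Tensor:
    """Non-overlapping max pooling along axis 1; trailing remainder dropped.

    Ties route the gradient to the earliest maximal position.
    """
    B, L, C = x.data.shape
    if pool >= L:               # global max over the length axis
        idx = x.data.argmax(axis=1)         # (B, C)
        out = Tensor(np.take_along_axis(x.data, idx[:, None, :], axis=1),
                     parents=(x,))

        def bw_global(g):
            full = np.zeros_like(x.data)
            np.put_along_axis(full, idx[:, None, :], g, axis=1)
            x._accum(full)

        out._backward = bw_global
        return out
    Lo = L // pool
    xv = x.data[:, :Lo * pool, :].reshape(B, Lo, pool, C)
    idx = xv.argmax(axis=2)                 # (B, Lo, C)
    out = Tensor(np.take_along_axis(xv, idx[:, :, None, :], axis=2)[:, :, 0, :],
                 parents=(x,))

    def bw(g):
        gx = np.zeros((B, Lo, pool, C))
        np.put_along_axis(gx, idx[:, :, None, :], g[:, :, None, :], axis=2)
        full = np.zeros_like(x.data)
        full[:, :Lo * pool, :] = gx.reshape(B, Lo * pool, C)
        x._accum(full)

    out._backward = bw
    return out


def conv1d(x: Tensor, W: Tensor, b: Tensor, width: int) -> Tensor:
    """'Same'-padded 1-D convolution over (B, L, C_in) with kernel
    ``W`` of shape (width * C_in, C_out), expressed as a sum of shifted
    matrix products so no large window copies are materialized."""
    B, L, C = x.data.shape
    Cout = W.data.shape[1]
    left = (width - 1) // 2
    xp = np.pad(x.data, ((0, 0), (left, width - 1 - left), (0, 0)))
    out_data = np.broadcast_to(b.data, (B, L, Cout)).copy()
    for j in range(width):
        out_data += xp[:, j:j + L, :] @ W.data[j * C:(j + 1) * C, :]
    out = Tensor(out_data, parents=(x, W, b))

    def bw(g):
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 1)))
        if W.requires_grad:
            gW = np.empty_like(W.data)
            for j in range(width):
                xs = xp[:, j:j + L, :].reshape(B * L, C)
                gW[j * C:(j + 1) * C, :] = xs.T @ g.reshape(B * L, Cout)
            W._accum(gW)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for j in range(width):
                gxp[:, j:j + L, :] += g @ W.data[j * C:(j + 1) * C, :].T
            x._accum(gxp[:, left:left + L, :])

    out._backward = bw
    return out


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gain.data + bias.data, parents=(x, gain, bias))
    D = x.data.shape[-1]

    def bw(g):
        if gain.requires_grad:
            gain._accum(_unbroadcast(g * xhat, gain.data.shape))
        if bias.requires_grad:
            bias._accum(_unbroadcast(g, bias.data.shape))
        if x.requires_grad:
            gh = g * gain.data
            x._accum(inv * (gh - gh.mean(axis=-1, keepdims=True)
                            - xhat * (gh * xhat).mean(axis=-1, keepdims=True)))
        _ = D

    out._backward = bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    out = Tensor(x.data * mask, parents=(x,))
    out._backward = lambda g: x._accum(g * mask)
    return out


def zero_grads(params) -> None:
    for p in params:
        p.grad = None


class no_grad_params:
    """Context manager that detaches parameters so no gradient flows to them.

    Used during inner (input-space) gradient ascent, where only the input
    logits need gradients and back-propagating into the weights would both
    waste time and pollute their accumulated gradients.
    """

    def __init__(self, params):
        self.params = list(params)

    def __enter__(self):
        self._saved = [p.requires_grad for p in self.params]
        for p in self.params:
            p.requires_grad = False
        return self

    def __exit__(self, *exc):
        for p, s in zip(self.params, self._saved):
            p.requires_grad = s
        return False


def clipped_exp(x: Tensor, cap: float = 10.0) -> Tensor:
    """exp(x) with the argument clipped at ``cap`` for overflow safety.

    Used as the first-layer convolution activation: motif occupancy is
    exponential in a site's log-odds score, so an exponential activation
    matches the physics of binding far better than a rectifier.
    """
    z = np.minimum(x.data, cap)
    out = Tensor(np.exp(z), parents=(x,))
    out._backward = lambda g: x._accum(g * out.data * (x.data < cap))
    return out
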