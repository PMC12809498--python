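"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operator set the volumetric transformer needs:
broadcast-aware arithmetic, batched matmul, reshape/transpose/slicing,
reflection padding, softmax, tanh/exp/erf-free GELU, reductions, an
elementwise maximum, and a 3D cross-correlation (convolution) primitive
with optional dilation.  Gradients are accumulated through a topologically
sorted tape; every op stores a closure that pushes its output gradient to
its parents.

Float32 throughout; this engine is written for small volumes and token
grids, not for large-scale training.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv3d", "pad_reflect3d", "softmax", "gelu", "maximum", "cat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo, seen = [], set()

        def visit(t: "Tensor") -> None:
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and (p.requires_grad or p._parents):
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self._accum(np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.expand_dims(g, -1) * b
            gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.expand_dims(a, -1) * g
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))
        out._backward = bw
        return out

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        out._backward = bw
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ----------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - out.data**2))
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * 0.5 / np.maximum(out.data, 1e-12))
        return out


# ---------------------------------------------------------------------------
# functional ops

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    y = np.exp(shifted)
    y /= y.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(x,))

    def bw(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accum(y * (g - dot))
    out._backward = bw
    return out


def gelu(x: Tensor) -> Tensor:
    """tanh-approximation GELU."""
    c = np.float32(np.sqrt(2.0 / np.pi))
    inner = (x * c) * (1.0 + 0.044715 * x * x)
    t = inner.tanh()
    return x * 0.5 * (1.0 + t)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    out_data = np.maximum(a.data, b.data)
    out = Tensor(out_data, parents=(a, b))
    a_wins = a.data >= b.data

    def bw(g):
        a._accum(_unbroadcast(np.where(a_wins, g, 0.0), a.data.shape))
        b._accum(_unbroadcast(np.where(a_wins, 0.0, g), b.data.shape))
    out._backward = bw
    return out


def cat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)
    out._backward = bw
    return out


def _reflect_index(n: int, pad_lo: int, pad_hi: int) -> np.ndarray:
    idx = np.arange(-pad_lo, n + pad_hi)
    period = 2 * n - 2 if n > 1 else 1
    idx = np.abs(idx) % period
    return np.where(idx >= n, period - idx, idx)


def pad_reflect3d(x: Tensor, pads: tuple[tuple[int, int], ...]) -> Tensor:
    """Reflection-pad the last three axes of (B, C, D, H, W)."""
    n3 = x.data.shape[-3:]
    idx = [_reflect_index(n, lo, hi) for n, (lo, hi) in zip(n3, pads)]
    out_data = x.data[..., idx[0], :, :][..., :, idx[1], :][..., :, :, idx[2]]
    out = Tensor(out_data, parents=(x,))
    # backward scatters through a flat index map of the gather
    flat_map = (idx[0][:, None, None] * (n3[1] * n3[2])
                + idx[1][None, :, None] * n3[2]
                + idx[2][None, None, :])

    def bw(g):
        lead = x.data.shape[:-3]
        full = np.zeros(lead + (n3[0] * n3[1] * n3[2],), dtype=np.float32)
        gflat = g.reshape(lead + (-1,))
        np.add.at(full, (..., flat_map.ravel()), gflat)
        x._accum(full.reshape(x.data.shape))
    out._backward = bw
    return out


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           dilation: int = 1) -> Tensor:
    """'Same'-size 3D cross-correlation with zero padding.

    x: (B, Cin, D, H, W); weight: (Cout, Cin, k, k, k) with odd k.
    Implemented through a precomputed gather-index table so that the
    backward pass is an exact scatter-add of the forward gather.
    """
    B, Cin, D, H, W = x.data.shape
    Cout, Cin_w, k, _, _ = weight.data.shape
    if Cin != Cin_w:
        raise ValueError("channel mismatch")
    if k % 2 == 0:
        raise ValueError("kernel size must be odd")
    pad = dilation * (k // 2)
    Dp, Hp, Wp = D + 2 * pad, H + 2 * pad, W + 2 * pad
    xp = np.zeros((B, Cin, Dp, Hp, Wp), dtype=np.float32)
    xp[:, :, pad:pad + D, pad:pad + H, pad:pad + W] = x.data

    taps = (np.arange(k) * dilation)
    di = (np.arange(D)[:, None] + taps[None, :])  # (D, k)
    hi = (np.arange(H)[:, None] + taps[None, :])
    wi = (np.arange(W)[:, None] + taps[None, :])
    # gather windows: (B, Cin, D, k, H, k, W, k)
    win = xp[:, :, di[:, :, None, None, None, None],
             hi[None, None, :, :, None, None],
             wi[None, None, None, None, :, :]]
    # -> (B, Cin, D, H, W, k, k, k)
    win = win.transpose(0, 1, 2, 4, 6, 3, 5, 7)
    out_data = np.einsum("bcdhwxyz,ocxyz->bodhw", win, weight.data,
                         optimize=True)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None, None]
    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(out_data, parents=parents)

    def bw(g):
        weight._accum(np.einsum("bodhw,bcdhwxyz->ocxyz", g, win, optimize=True))
        if bias is not None:
            bias._accum(g.sum(axis=(0, 2, 3, 4)))
        # gradient wrt x: scatter each tap's contribution back into xp
        gw = np.einsum("bodhw,ocxyz->bcdhwxyz", g, weight.data, optimize=True)
        gxp = np.zeros_like(xp)
        for a in range(k):
            for b_ in range(k):
                for c_ in range(k):
                    gxp[:, :,
                        a * dilation:a * dilation + D,
                        b_ * dilation:b_ * dilation + H,
                        c_ * dilation:c_ * dilation + W] += gw[:, :, :, :, :, a, b_, c_]
        x._accum(gxp[:, :, pad:pad + D, pad:pad + H, pad:pad + W])
    out._backward = bw
    return out
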