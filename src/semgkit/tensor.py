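"""A minimal reverse-mode automatic-differentiation engine on NumPy arrays.

Everything is float64. A :class:`Tensor` wraps an ndarray and records the
operations applied to it; :meth:`Tensor.backward` runs reverse-mode
accumulation over the recorded tape (topological order, gradients summed
at fan-in). The op set is exactly what the network layers need:
broadcast-aware arithmetic, two-operand einsum (which also covers matmul
and the locally-connected layer), 3x3 same-padded convolution patches,
elementwise nonlinearities, reductions, reshapes, indexing and
concatenation.

Broadcasting gradients are reduced back to the operand's shape by
summing over broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "einsum2", "conv2d_same3", "softmax", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- basic protocol ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autodiff ------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient only on scalars")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS (graphs can be deep: LSTM over T steps)
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=float)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._parents == () or node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data
        return Tensor(
            out_data,
            parents=(self, other),
            backward=lambda g: (
                _unbroadcast(g, self.data.shape),
                _unbroadcast(g, other.data.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data * other.data,
            parents=(self, other),
            backward=lambda g: (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data / other.data,
            parents=(self, other),
            backward=lambda g: (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            ),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        return Tensor(
            self.data**exponent,
            parents=(self,),
            backward=lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        if self.ndim == 2 and other.ndim == 2:
            return einsum2("ij,jk->ik", self, other)
        raise ValueError("matmul supports 2-D operands; use einsum2 for batched forms")

    # -- elementwise ---------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor(out_data, parents=(self,), backward=lambda g: (g * out_data,))

    def log(self):
        return Tensor(np.log(self.data), parents=(self,), backward=lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor(out_data, parents=(self,), backward=lambda g: (g / (2.0 * out_data),))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor(out_data, parents=(self,), backward=lambda g: (g * (1.0 - out_data**2),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(
            out_data, parents=(self,), backward=lambda g: (g * out_data * (1.0 - out_data),)
        )

    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, parents=(self,), backward=lambda g: (g * mask,))

    def clip_min(self, lo: float):
        """max(x, lo) elementwise; gradient passes where x > lo."""
        mask = self.data > lo
        return Tensor(
            np.maximum(self.data, lo), parents=(self,), backward=lambda g: (g * mask,)
        )

    # -- reductions / shape --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            gg = g
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % self.data.ndim for a in axes)
                for a in sorted(axes):
                    gg = np.expand_dims(gg, a)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        return Tensor(out_data, parents=(self,), backward=backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor(
            self.data.reshape(shape),
            parents=(self,),
            backward=lambda g: (g.reshape(self.data.shape),),
        )

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor(
            self.data.transpose(axes),
            parents=(self,),
            backward=lambda g: (g.transpose(inv),),
        )

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        def backward(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, idx, g)
            return (gx,)

        return Tensor(self.data[idx], parents=(self,), backward=backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=backward,
    )


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def backward(g):
        return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))

    return Tensor(
        np.stack([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=backward,
    )


def einsum2(spec: str, a, b) -> Tensor:
    """Two-operand einsum with reverse-mode gradients.

    Each index of an operand must appear in the output or in the other
    operand (no internal diagonals/traces), which holds for matmul,
    batched matmul and locally-connected contractions.
    """
    a, b = as_tensor(a), as_tensor(b)
    ins, out_sub = spec.replace(" ", "").split("->")
    s1, s2 = ins.split(",")

    def backward(g):
        ga = np.einsum(f"{out_sub},{s2}->{s1}", g, b.data)
        gb = np.einsum(f"{out_sub},{s1}->{s2}", g, a.data)
        return ga, gb

    return Tensor(np.einsum(spec, a.data, b.data), parents=(a, b), backward=backward)


def conv2d_same3(x, weight, bias) -> Tensor:
    """3x3 convolution, stride 1, zero same-padding.

    ``x``: (B, C_in, H, W); ``weight``: (C_out, C_in, 3, 3);
    ``bias``: (C_out,). Output: (B, C_out, H, W).
    """
    x, weight, bias = as_tensor(x), as_tensor(weight), as_tensor(bias)
    B, Cin, H, W = x.data.shape
    Cout = weight.data.shape[0]
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)))
    # im2col: (B, Cin, H, W, 3, 3) view -> (B*H*W, Cin*9) matrix, so the
    # contraction runs through BLAS instead of a 6-index einsum
    patches = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    cols = np.ascontiguousarray(patches.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B * H * W, Cin * 9
    )
    wmat = weight.data.reshape(Cout, Cin * 9)
    out_data = (cols @ wmat.T).reshape(B, H, W, Cout).transpose(0, 3, 1, 2) + bias.data[
        None, :, None, None
    ]

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * H * W, Cout)
        gw = (gmat.T @ cols).reshape(weight.data.shape)
        gb = g.sum(axis=(0, 2, 3))
        gcols = (gmat @ wmat).reshape(B, H, W, Cin, 3, 3).transpose(0, 3, 1, 2, 4, 5)
        gxp = np.zeros_like(xp)
        for p in range(3):
            for q in range(3):
                gxp[:, :, p : p + H, q : q + W] += gcols[:, :, :, :, p, q]
        return gxp[:, :, 1:-1, 1:-1], gw, gb

    return Tensor(out_data, parents=(x, weight, bias), backward=backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis`` (max-shift is detached,
    which is exact because softmax is shift-invariant)."""
    shift = np.max(x.data, axis=axis, keepdims=True)
    e = (x - Tensor(shift)).exp()
    return e / e.sum(axis=axis, keepdims=True)
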