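"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough tensor calculus for a convolutional-recurrent regression
network: broadcast-aware arithmetic, matmul, 1-D convolution and max
pooling, the usual pointwise nonlinearities, reductions, slicing and
concatenation, plus an Adam optimizer.  Gradients are accumulated by a
topologically ordered backward sweep over the recorded tape.

Every operation's backward pass is exercised against central finite
differences in the test suite.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "use_dtype", "default_dtype"]

_DTYPE = np.float64


def default_dtype():
    return _DTYPE


@contextmanager
def use_dtype(dtype):
    """Run tape construction in the given float precision (the network is
    trained single precision; gradient checks run double)."""
    global _DTYPE
    prev = _DTYPE
    _DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        _DTYPE = prev


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
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_inplace")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None
        self._inplace = False  # backward accumulates into parent.grad itself

    # -- construction helpers ------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def reciprocal(self):
        inv = 1.0 / self.data
        return Tensor._from_op(inv, (self,), lambda g: (-g * inv * inv,))

    def __truediv__(self, other):
        return self * self._lift(other).reciprocal()

    def __rtruediv__(self, other):
        return self._lift(other) * self.reciprocal()

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            return g @ other.data.swapaxes(-1, -2), self.data.swapaxes(-1, -2) @ g

        return Tensor._from_op(out_data, (self, other), backward)

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape

        def backward(g):
            return (g.reshape(orig),)

        return Tensor._from_op(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            return (g.transpose(*inv),)

        return Tensor._from_op(self.data.transpose(*axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            # accumulate straight into the parent gradient; allocating a
            # full zero tensor per slice dominates backward cost otherwise
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            self.grad[idx] += g

        out = Tensor._from_op(self.data[idx], (self,), backward)
        out._inplace = True
        return out

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = -1) -> "Tensor":
        tensors = [Tensor._lift(t) for t in tensors]
        sizes = [t.data.shape[axis] for t in tensors]
        out_data = np.concatenate([t.data for t in tensors], axis=axis)
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            return tuple(np.split(g, splits, axis=axis))

        return Tensor._from_op(out_data, tensors, backward)

    # -- pointwise nonlinearities --------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._from_op(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._from_op(s, (self,), lambda g: (g * s * (1 - s),))

    def tanh(self):
        t = np.tanh(self.data)
        return Tensor._from_op(t, (self,), lambda g: (g * (1 - t * t),))

    def exp(self):
        e = np.exp(self.data)
        return Tensor._from_op(e, (self,), lambda g: (g * e,))

    def log(self):
        return Tensor._from_op(np.log(self.data), (self,), lambda g: (g / self.data,))

    def softplus(self):
        # numerically stable log(1 + e^x)
        out = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._from_op(out, (self,), lambda g: (g * sig,))

    def sqrt(self):
        r = np.sqrt(self.data)
        return Tensor._from_op(r, (self,), lambda g: (g / (2.0 * r),))

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max_pool1d(self, kernel: int = 2):
        """Non-overlapping max pooling over the last axis (trailing
        remainder steps are dropped)."""
        L = self.shape[-1]
        L_out = L // kernel
        view = self.data[..., : L_out * kernel].reshape(
            self.shape[:-1] + (L_out, kernel)
        )
        arg = view.argmax(axis=-1)
        out_data = np.take_along_axis(view, arg[..., None], axis=-1)[..., 0]

        def backward(g):
            gv = np.zeros_like(view)
            np.put_along_axis(gv, arg[..., None], g[..., None], axis=-1)
            full = np.zeros_like(self.data)
            full[..., : L_out * kernel] = gv.reshape(self.shape[:-1] + (L_out * kernel,))
            return (full,)

        return Tensor._from_op(out_data, (self,), backward)

    def conv1d(self, weight: "Tensor", bias: "Tensor", stride: int) -> "Tensor":
        """1-D cross-correlation: input (N, C, L), weight (O, C, K) -> (N, O, L_out)."""
        x, w = self.data, weight.data
        K = w.shape[-1]
        win = np.lib.stride_tricks.sliding_window_view(x, K, axis=2)[:, :, ::stride]
        out_data = np.einsum("nclk,ock->nol", win, w) + bias.data[None, :, None]
        L_out = out_data.shape[-1]

        def backward(g):
            dw = np.einsum("nol,nclk->ock", g, win)
            db = g.sum(axis=(0, 2))
            t = np.einsum("nol,ock->nclk", g, w)
            dx = np.zeros_like(x)
            for k in range(K):
                dx[:, :, k : k + stride * L_out : stride] += t[:, :, :, k]
            return dx, dw, db

        return Tensor._from_op(out_data, (self, weight, bias), backward)

    # -- backward sweep ------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("implicit gradient only for scalars")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; tapes exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None:
                continue
            if node._inplace:
                node._backward(node.grad)
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g.copy()
                else:
                    parent.grad += g


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adaptive-momentum optimizer (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
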