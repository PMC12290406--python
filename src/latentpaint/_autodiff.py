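"""Minimal reverse-mode automatic differentiation over numpy arrays.

The inference modules need gradients of scalar losses with respect to latent
codes, decoder weights, and variational parameters.  No deep-learning framework
is assumed at runtime, so this module provides a small tape-based engine with
exactly the operations the package uses: broadcasting arithmetic, matmul,
reductions, elementwise transcendentals, basic slicing, 2-D correlation with a
fixed kernel, and stride-2 subsampling.

Gradient conventions follow the usual vector-Jacobian-product rules; every op
is validated against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve as _nd_convolve
from scipy.ndimage import correlate as _nd_correlate

__all__ = ["Tensor", "as_tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    grad = np.asarray(grad, dtype=float)
    if grad.shape == shape:
        return grad
    # sum away leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("value", "grad", "_parents", "requires_grad")

    def __init__(self, value, parents=(), requires_grad=False):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        self._parents = tuple(parents)
        self.requires_grad = requires_grad or any(
            p.requires_grad for p, _ in parents
        )

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p, _ in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.value)}
        for t in reversed(topo):
            g = grads.get(id(t))
            if g is None:
                continue
            t.grad = g if t.grad is None else t.grad + g
            for p, gfn in t._parents:
                if not p.requires_grad:
                    continue
                contrib = _unbroadcast(gfn(g), p.value.shape)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + contrib
                else:
                    grads[id(p)] = contrib

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        return Tensor(self.value + other.value,
                      [(self, lambda g: g), (other, lambda g: g)])

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.value, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor(self.value * other.value,
                      [(self, lambda g: g * other.value),
                       (other, lambda g: g * self.value)])

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor(self.value / other.value,
                      [(self, lambda g: g / other.value),
                       (other, lambda g: -g * self.value / other.value ** 2)])

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        return Tensor(self.value ** p,
                      [(self, lambda g: g * p * self.value ** (p - 1))])

    def __matmul__(self, other):
        other = as_tensor(other)
        if self.value.ndim != 2 or other.value.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")
        return Tensor(self.value @ other.value,
                      [(self, lambda g: g @ other.value.T),
                       (other, lambda g: self.value.T @ g)])

    def __getitem__(self, idx):
        def gfn(g, idx=idx, shape=self.value.shape):
            full = np.zeros(shape)
            full[idx] += g
            return full

        return Tensor(self.value[idx], [(self, gfn)])

    # -- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def gfn(g):
            if axis is None:
                return np.broadcast_to(g, self.value.shape)
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.value.shape)

        return Tensor(self.value.sum(axis=axis, keepdims=keepdims),
                      [(self, gfn)])

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor(self.value.reshape(shape),
                      [(self, lambda g: g.reshape(self.value.shape))])

    def ravel(self):
        return self.reshape(-1)

    # -- elementwise -----------------------------------------------------
    def exp(self):
        out = np.exp(self.value)
        return Tensor(out, [(self, lambda g: g * out)])

    def log(self):
        return Tensor(np.log(self.value), [(self, lambda g: g / self.value)])

    def sqrt(self):
        out = np.sqrt(self.value)
        return Tensor(out, [(self, lambda g: g * 0.5 / out)])

    def tanh(self):
        out = np.tanh(self.value)
        return Tensor(out, [(self, lambda g: g * (1.0 - out ** 2))])

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.value))
        return Tensor(out, [(self, lambda g: g * out * (1.0 - out))])

    def arccos(self, grad_eps: float = 1e-7):
        # value uses the hard clamp; the gradient clamp keeps 1/sqrt(1-x^2)
        # finite when the argument sits exactly on +-1
        x = np.clip(self.value, -1.0, 1.0)
        xg = np.clip(self.value, -1.0 + grad_eps, 1.0 - grad_eps)
        return Tensor(np.arccos(x),
                      [(self, lambda g: -g / np.sqrt(1.0 - xg ** 2))])

    def clip(self, lo: float, hi: float):
        inside = (self.value > lo) & (self.value < hi)
        return Tensor(np.clip(self.value, lo, hi),
                      [(self, lambda g: g * inside)])

    # -- image ops -------------------------------------------------------
    def conv2d(self, kernel: np.ndarray):
        """Same-size 2-D correlation with a fixed kernel, zero padding."""
        k = np.asarray(kernel, dtype=float)
        if self.value.ndim != 2:
            raise ValueError("conv2d expects a 2-D tensor")
        val = _nd_correlate(self.value, k, mode="constant", cval=0.0)
        return Tensor(val, [
            (self, lambda g: _nd_convolve(g, k, mode="constant", cval=0.0))])

    def downsample2(self):
        """Keep every second row/column (top-left phase)."""
        return self[::2, ::2]


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class Adam:
    """Adam optimizer over leaf tensors (lr default per run configuration)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)
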