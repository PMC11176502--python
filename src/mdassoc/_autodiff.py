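"""Minimal reverse-mode automatic differentiation on numpy arrays.

The graph models trained here (variational graph autoencoder, graph
attention refinement) need gradients of a handful of dense-matrix
operations.  This module provides exactly that set: matmul, elementwise
arithmetic, leaky ReLU, sigmoid, (masked) row softmax, and two fused,
numerically stable loss primitives (weighted binary cross-entropy on
logits, and the Gaussian KL term of the ELBO), plus an Adam optimizer.

Values are float64 numpy arrays throughout; a `Tensor` wraps a value and
accumulates `grad` during `backward()`.  Broadcasting is supported for
elementwise ops (gradients are summed back over broadcast axes).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "matmul",
    "add",
    "mul",
    "scale",
    "leaky_relu",
    "sigmoid",
    "exp",
    "softmax_rows",
    "masked_softmax_rows",
    "weighted_bce_with_logits",
    "gaussian_kl",
    "row_mix",
    "Adam",
]


class Tensor:
    """A node in the computation graph.

    ``requires_grad`` marks trainable leaves; interior nodes always
    propagate gradients to parents that need them.
    """

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, value, *, requires_grad=False, parents=(), backward=None, name=""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.value.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape}, name={self.name!r})"

    # -- graph traversal ------------------------------------------------
    def backward(self):
        """Accumulate gradients of this (scalar) tensor w.r.t. all leaves."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for node in order:
            node.grad = np.zeros_like(node.value)
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)

    # operator sugar for the few composites used in model code
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)


def constant(value, name=""):
    return Tensor(value, name=name)


def parameter(value, name=""):
    return Tensor(np.array(value, dtype=np.float64, copy=True), requires_grad=True, name=name)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_val = a.value @ b.value

    def backward(g):
        if a._backward is not None or a.requires_grad:
            a.grad += g @ b.value.T
        if b._backward is not None or b.requires_grad:
            b.grad += a.value.T @ g

    return Tensor(out_val, parents=(a, b), backward=backward)


def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_val = a.value + b.value

    def backward(g):
        a.grad += _unbroadcast(g, a.value.shape)
        b.grad += _unbroadcast(g, b.value.shape)

    return Tensor(out_val, parents=(a, b), backward=backward)


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_val = a.value * b.value

    def backward(g):
        a.grad += _unbroadcast(g * b.value, a.value.shape)
        b.grad += _unbroadcast(g * a.value, b.value.shape)

    return Tensor(out_val, parents=(a, b), backward=backward)


def scale(a, c):
    a = _as_tensor(a)
    c = float(c)

    def backward(g):
        a.grad += c * g

    return Tensor(a.value * c, parents=(a,), backward=backward)


def leaky_relu(x, slope=0.2):
    x = _as_tensor(x)
    out_val = np.where(x.value > 0, x.value, slope * x.value)

    def backward(g):
        x.grad += np.where(x.value > 0, 1.0, slope) * g

    return Tensor(out_val, parents=(x,), backward=backward)


def sigmoid(x):
    x = _as_tensor(x)
    out_val = _sigmoid(x.value)

    def backward(g):
        x.grad += out_val * (1.0 - out_val) * g

    return Tensor(out_val, parents=(x,), backward=backward)


def exp(x):
    x = _as_tensor(x)
    out_val = np.exp(x.value)

    def backward(g):
        x.grad += out_val * g

    return Tensor(out_val, parents=(x,), backward=backward)


def _sigmoid(v):
    out = np.empty_like(v)
    pos = v >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-v[pos]))
    ev = np.exp(v[~pos])
    out[~pos] = ev / (1.0 + ev)
    return out


def softmax_rows(x):
    x = _as_tensor(x)
    shifted = x.value - x.value.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    out_val = e / e.sum(axis=1, keepdims=True)

    def backward(g):
        dot = (g * out_val).sum(axis=1, keepdims=True)
        x.grad += out_val * (g - dot)

    return Tensor(out_val, parents=(x,), backward=backward)


def masked_softmax_rows(x, mask):
    """Row softmax restricted to ``mask`` (bool array, constant).

    Entries outside the mask are 0 in the output; rows whose mask is
    empty come out all-zero (the caller decides what an isolated node
    does).
    """
    x = _as_tensor(x)
    mask = np.asarray(mask, dtype=bool)
    neg = np.where(mask, x.value, -np.inf)
    row_max = np.max(neg, axis=1, keepdims=True)
    row_max = np.where(np.isfinite(row_max), row_max, 0.0)
    e = np.where(mask, np.exp(neg - row_max), 0.0)
    denom = e.sum(axis=1, keepdims=True)
    safe = np.where(denom > 0, denom, 1.0)
    out_val = e / safe

    def backward(g):
        dot = (g * out_val).sum(axis=1, keepdims=True)
        x.grad += np.where(mask, out_val * (g - dot), 0.0)

    return Tensor(out_val, parents=(x,), backward=backward)


def weighted_bce_with_logits(logits, targets, pos_weight=1.0):
    """Mean binary cross-entropy on logits with a positive-class weight.

    loss = mean( w·t·softplus(-l) + (1-t)·softplus(l) ),  w = pos_weight.
    Stable for large |l|; gradient is (σ(l)·(w·t + 1 - t) - w·t)/N.
    """
    logits = _as_tensor(logits)
    t = np.asarray(targets, dtype=np.float64)
    w = float(pos_weight)
    l = logits.value
    softplus_neg = np.logaddexp(0.0, -l)
    softplus_pos = np.logaddexp(0.0, l)
    per = w * t * softplus_neg + (1.0 - t) * softplus_pos
    n = per.size
    out_val = per.sum() / n

    def backward(g):
        s = _sigmoid(l)
        logits.grad += g * (s * (w * t + 1.0 - t) - w * t) / n

    return Tensor(out_val, parents=(logits,), backward=backward)


def gaussian_kl(mu, log_var):
    """KL( N(mu, diag exp(log_var)) || N(0, I) ), summed over all entries.

    Closed form: -0.5 · Σ (1 + log σ² − μ² − σ²).  Always ≥ 0.
    """
    mu, log_var = _as_tensor(mu), _as_tensor(log_var)
    var = np.exp(log_var.value)
    out_val = -0.5 * np.sum(1.0 + log_var.value - mu.value**2 - var)

    def backward(g):
        mu.grad += g * mu.value
        log_var.grad += g * (-0.5) * (1.0 - var)

    return Tensor(out_val, parents=(mu, log_var), backward=backward)


def row_mix(keep_rows, a, b):
    """Select rows: output row i is a[i] where keep_rows[i] else b[i]."""
    a, b = _as_tensor(a), _as_tensor(b)
    keep = np.asarray(keep_rows, dtype=bool).reshape(-1, 1)
    out_val = np.where(keep, a.value, b.value)

    def backward(g):
        a.grad += np.where(keep, g, 0.0)
        b.grad += np.where(keep, 0.0, g)

    return Tensor(out_val, parents=(a, b), backward=backward)


class Adam:
    """Adam with the standard bias correction (β1=0.9, β2=0.999)."""

    def __init__(self, params, lr=0.01, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if g is None:
                continue
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            m_hat = m / (1 - self.beta1**self.t)
            v_hat = v / (1 - self.beta2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
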