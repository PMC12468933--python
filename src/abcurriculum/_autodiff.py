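"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough operator coverage for a pre-LayerNorm transformer encoder with
rotary or learned-absolute position embeddings, an MLM head and a small
classification head: broadcast add/mul, batched matmul, layer norm, GELU,
tanh, softmax, embedding lookup, rotary rotation, reshape/transpose/slicing,
and a fused softmax-cross-entropy loss.  Gradients are accumulated by
reverse topological sweep; every primitive's backward rule is exercised by a
finite-difference check in the test suite.

This is intentionally a small engine, not a framework: no graph reuse, no
higher-order gradients, float64 throughout (desk-scale models are tiny, so
precision is cheaper than speed tuning).
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "param", "const", "matmul", "layer_norm", "gelu", "tanh",
           "softmax", "embedding", "rope_rotate", "select_position",
           "cross_entropy_logits", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Optional[Callable[[np.ndarray], None]] = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
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
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))
        return _node(out_data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))
        return _node(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def reshape(self, *shape):
        orig = self.shape
        out_data = self.data.reshape(*shape)

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))
        return _node(out_data, (self,), bw)

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out_data = self.data.transpose(*axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))
        return _node(out_data, (self,), bw)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=parents,
                  backward=backward if req else None)


def param(data, rng: Optional[np.random.Generator] = None,
          scale: Optional[float] = None) -> Tensor:
    """Create a trainable parameter; with ``rng``, ``data`` is a shape."""
    if rng is not None:
        shape = tuple(data)
        std = scale if scale is not None else 1.0 / np.sqrt(shape[-1])
        data = rng.normal(0.0, std, size=shape)
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def const(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bw(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.shape))
    return _node(out_data, (a, b), bw)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = xhat * gamma.data + beta.data

    def bw(g):
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.shape))
        if x.requires_grad:
            n = x.data.shape[-1]
            gx = g * gamma.data
            dx = inv * (gx - gx.mean(axis=-1, keepdims=True)
                        - xhat * (gx * xhat).mean(axis=-1, keepdims=True))
            # note: uses population variance, hence the two mean corrections
            x._accum(dx)
    return _node(out_data, (x, gamma, beta), bw)


_SQRT2 = np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x: Tensor) -> Tensor:
    cdf = 0.5 * (1.0 + erf(x.data / _SQRT2))
    out_data = x.data * cdf

    def bw(g):
        if x.requires_grad:
            pdf = _INV_SQRT2PI * np.exp(-0.5 * x.data ** 2)
            x._accum(g * (cdf + x.data * pdf))
    return _node(out_data, (x,), bw)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def bw(g):
        if x.requires_grad:
            x._accum(g * (1.0 - out_data ** 2))
    return _node(out_data, (x,), bw)


def softmax(x: Tensor, bias: Optional[np.ndarray] = None) -> Tensor:
    """Softmax over the last axis; ``bias`` is an additive constant (e.g. an
    attention mask of 0 / -inf surrogates) that receives no gradient."""
    z = x.data if bias is None else x.data + bias
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=-1, keepdims=True)

    def bw(g):
        if x.requires_grad:
            dot = (g * out_data).sum(axis=-1, keepdims=True)
            x._accum(out_data * (g - dot))
    return _node(out_data, (x,), bw)


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    ids = np.asarray(ids)
    out_data = weight.data[ids]

    def bw(g):
        if weight.requires_grad:
            gw = np.zeros_like(weight.data)
            np.add.at(gw, ids.reshape(-1), g.reshape(-1, g.shape[-1]))
            weight._accum(gw)
    return _node(out_data, (weight,), bw)


def rope_rotate(x: Tensor, cos: np.ndarray, sin: np.ndarray) -> Tensor:
    """Rotary rotation ``x*cos + rotate_half(x)*sin`` on the last axis.

    ``rotate_half([x1, x2]) = [-x2, x1]`` over the two halves of the head
    dimension; cos/sin are position-dependent constants.
    """
    d = x.data.shape[-1]
    h = d // 2

    def rot(v):
        return np.concatenate([-v[..., h:], v[..., :h]], axis=-1)

    out_data = x.data * cos + rot(x.data) * sin

    def bw(g):
        if x.requires_grad:
            # adjoint of v -> rot(v)*sin: weight by sin, then rotate back
            gs = g * sin
            gr = np.concatenate([gs[..., h:], -gs[..., :h]], axis=-1)
            x._accum(g * cos + gr)
    return _node(out_data, (x,), bw)


def select_position(x: Tensor, pos: int) -> Tensor:
    """Pick one sequence position: (B, T, H) -> (B, H)."""
    out_data = x.data[:, pos, :]

    def bw(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[:, pos, :] = g
            x._accum(gx)
    return _node(out_data, (x,), bw)


def cross_entropy_logits(logits: Tensor, labels: np.ndarray,
                         ignore_index: int = -100):
    """Mean cross entropy over positions with ``labels != ignore_index``.

    Returns ``(loss_tensor, n_counted)``; with no counted positions the loss
    is 0 with zero gradient.
    """
    labels = np.asarray(labels)
    flat_logits = logits.data.reshape(-1, logits.data.shape[-1])
    flat_labels = labels.reshape(-1)
    mask = flat_labels != ignore_index
    n = int(mask.sum())
    z = flat_logits - flat_logits.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1))
    probs = np.exp(z) / np.exp(z).sum(axis=-1, keepdims=True)
    if n == 0:
        loss_val = 0.0
    else:
        idx = np.flatnonzero(mask)
        picked = z[idx, flat_labels[idx]]
        loss_val = float((logsumexp[idx] - picked).mean())

    def bw(g):
        if logits.requires_grad and n > 0:
            grad = np.zeros_like(flat_logits)
            idx = np.flatnonzero(mask)
            grad[idx] = probs[idx]
            grad[idx, flat_labels[idx]] -= 1.0
            grad /= n
            logits._accum((g * grad).reshape(logits.data.shape))
    return _node(np.float64(loss_val), (logits,), bw), n


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: Optional[float] = None) -> None:
        if lr is not None:
            self.lr = lr
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
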