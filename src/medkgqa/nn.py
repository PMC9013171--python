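"""Minimal reverse-mode autodiff over numpy arrays.

The package's neural components (sequence tagger, relation CNN, paragraph
vectors, tuple encoder, QA heads) are small enough that a compact tape-based
engine is sufficient: tensors wrap numpy arrays, every differentiable op
records a local backward closure, and ``Tensor.backward`` walks the tape in
reverse topological order.  Broadcasting follows numpy semantics; gradients
of broadcast operands are summed back to the operand shape.

Only the ops the models need are provided — this is not a general framework.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
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


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # ---- basic introspection -------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # ---- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        return self * (as_tensor(other) ** -1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * (self ** -1.0)

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        """Matrix product for the 1D/2D cases the models use."""
        other = as_tensor(other)
        a, b = self.data, other.data
        out = Tensor(a @ b, _prev=(self, other))

        def bw(g):
            g = np.asarray(g)
            if self.requires_grad:
                if a.ndim == 1 and b.ndim == 1:
                    self._accum(g * b)
                elif a.ndim == 1:          # (k,) @ (k,n) -> (n,)
                    self._accum(g @ b.T)
                elif b.ndim == 1:          # (m,k) @ (k,) -> (m,)
                    self._accum(np.outer(g, b))
                else:                      # (m,k) @ (k,n)
                    self._accum(g @ b.T)
            if other.requires_grad:
                if a.ndim == 1 and b.ndim == 1:
                    other._accum(g * a)
                elif a.ndim == 1:
                    other._accum(np.outer(a, g))
                elif b.ndim == 1:
                    other._accum(a.T @ g)
                else:
                    other._accum(a.T @ g)

        out._backward = bw
        return out

    # ---- elementwise nonlinearities ------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - y * y))

        out._backward = bw
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * y * (1.0 - y))

        out._backward = bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        out._backward = bw
        return out

    def exp(self):
        y = np.exp(np.clip(self.data, -700, 700))
        out = Tensor(y, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * y)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = bw
        return out

    def sqrt(self):
        return self ** 0.5

    # ---- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                g = np.asarray(g)
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        out = Tensor(out_data, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                g = np.asarray(g)
                full = out_data if keepdims or axis is None else np.expand_dims(out_data, axis)
                mask = (self.data == full)
                mask = mask / mask.sum(axis=axis, keepdims=True)  # split ties
                gfull = g if keepdims or axis is None else np.expand_dims(g, axis)
                self._accum(mask * gfull)

        out._backward = bw
        return out

    def logsumexp(self, axis=-1, keepdims=False):
        m = self.data.max(axis=axis, keepdims=True)
        y = m + np.log(np.exp(self.data - m).sum(axis=axis, keepdims=True))
        out = Tensor(y if keepdims else np.squeeze(y, axis=axis), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                soft = np.exp(self.data - y)
                gfull = np.asarray(g)
                if not keepdims:
                    gfull = np.expand_dims(gfull, axis)
                self._accum(soft * gfull)

        out._backward = bw
        return out

    # ---- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def ravel(self):
        return self.reshape(-1)

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bw
        return out

    # ---- autodiff driver -------------------------------------------------
    def backward(self):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def bw(g):
        start = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, start + s)
                t._accum(g[tuple(sl)])
            start += s

    out._backward = bw
    return out


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _prev=tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out._backward = bw
    return out


def softmax(t: Tensor, axis=-1) -> Tensor:
    return (t - t.logsumexp(axis=axis, keepdims=True)).exp()


def log_softmax(t: Tensor, axis=-1) -> Tensor:
    return t - t.logsumexp(axis=axis, keepdims=True)


def hinge(x: Tensor) -> Tensor:
    """max(0, x), elementwise."""
    return x.relu()


# ---------------------------------------------------------------------------
# Parameters and optimisation
# ---------------------------------------------------------------------------

class Param(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def init_matrix(rng: np.random.Generator, n_in: int, n_out: int, scale=None) -> Param:
    scale = scale if scale is not None else np.sqrt(2.0 / (n_in + n_out))
    return Param(rng.normal(0.0, scale, size=(n_in, n_out)))


class Adam:
    """Adam optimiser over a flat dict of Params."""

    def __init__(self, params: dict, lr=0.01, betas=(0.9, 0.999), eps=1e-8,
                 clip_norm: float | None = 5.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        grads = {k: (p.grad if p.grad is not None else np.zeros_like(p.data))
                 for k, p in self.params.items()}
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def lstm_step(params: dict, prefix: str, x: Tensor, h_prev: Tensor, c_prev: Tensor,
              bridge: Tensor | None = None):
    """One LSTM step for a batch.

    `x` (B, D), `h_prev`/`c_prev` (B, H).  When `bridge` is given (B, H) the
    cell state receives the gated additive pattern term
    c_t = c_t_orig + p_t * bridge with p_t = sigma(W_pi [h_prev, x] + W_pc c_prev + b_p).
    Returns (h_t, c_t).
    """
    z = concat([h_prev, x], axis=1)
    gates = z @ params[prefix + "W"] + params[prefix + "b"]
    H = h_prev.shape[1]
    i = gates[:, 0 * H:1 * H].sigmoid()
    f = gates[:, 1 * H:2 * H].sigmoid()
    o = gates[:, 2 * H:3 * H].sigmoid()
    g = gates[:, 3 * H:4 * H].tanh()
    c = f * c_prev + i * g
    if bridge is not None:
        p_t = (z @ params[prefix + "W_pi"] + c_prev @ params[prefix + "W_pc"]
               + params[prefix + "b_p"]).sigmoid()
        c = c + p_t * bridge
    h = o * c.tanh()
    return h, c


def init_lstm(rng: np.random.Generator, params: dict, prefix: str, d_in: int,
              d_hidden: int, with_bridge: bool = False):
    params[prefix + "W"] = init_matrix(rng, d_in + d_hidden, 4 * d_hidden)
    params[prefix + "b"] = Param(np.zeros(4 * d_hidden))
    # forget-gate bias 1: standard stabilisation on short corpora
    params[prefix + "b"].data[d_hidden:2 * d_hidden] = 1.0
    if with_bridge:
        params[prefix + "W_pi"] = init_matrix(rng, d_in + d_hidden, d_hidden)
        params[prefix + "W_pc"] = init_matrix(rng, d_hidden, d_hidden)
        params[prefix + "b_p"] = Param(np.zeros(d_hidden))
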