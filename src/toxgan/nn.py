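"""Minimal reverse-mode autodiff on NumPy arrays, with the layers the
generator and critic need (linear, batch normalization, dropout).

The vector-Jacobian products are themselves expressed in tensor operations,
so gradients of gradients work — required for the gradient penalty, whose
loss contains the norm of the critic's input gradient.

Only what the adversarial training loop uses is implemented: 2-D matmul,
broadcasting elementwise arithmetic, reductions, tanh / leaky-ReLU /
sigmoid / log, concatenation and slicing.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "grad",
    "Linear",
    "BatchNorm1d",
    "Dropout",
    "Adam",
]


class Tensor:
    """An array node in a computation graph."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjps")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple = (),
        _vjps: tuple = (),
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._vjps = _vjps

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        return _add(self, _as_tensor(other))

    __radd__ = __add__

    def __neg__(self):
        return _mul(self, Tensor(-1.0))

    def __sub__(self, other):
        return _add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return _add(_as_tensor(other), -self)

    def __mul__(self, other):
        return _mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _mul(self, _as_tensor(other) ** -1.0)

    def __rtruediv__(self, other):
        return _mul(_as_tensor(other), self ** -1.0)

    def __pow__(self, p: float):
        return _pow(self, float(p))

    def __matmul__(self, other):
        return _matmul(self, _as_tensor(other))

    def __getitem__(self, key):
        return _slice(self, key)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return _reshape(self, shape)

    @property
    def T(self):
        return _transpose(self)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        return _sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return _sum(self, axis, keepdims) * (1.0 / n)

    # -- nonlinearities ------------------------------------------------------
    def tanh(self):
        return _tanh(self)

    def sigmoid(self):
        return _sigmoid(self)

    def log(self):
        return _log(self)

    def sqrt(self):
        return _pow(self, 0.5)

    def leaky_relu(self, negative_slope: float = 0.2):
        return _leaky_relu(self, negative_slope)

    def minimum(self, bound: float):
        return _clip_op(self, bound, np.minimum, np.less)

    def maximum(self, bound: float):
        return _clip_op(self, bound, np.maximum, np.greater)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents: tuple, vjps: tuple) -> Tensor:
    """Build an op node, dropping the graph when no parent is differentiable."""
    if any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, _parents=parents, _vjps=vjps)
    return Tensor(data)


def _sum_to_shape(t: Tensor, shape: tuple) -> Tensor:
    """Reduce a broadcast cotangent back to the parent's shape."""
    if t.data.shape == shape:
        return t
    extra = t.data.ndim - len(shape)
    axes = tuple(range(extra)) + tuple(
        i + extra
        for i, s in enumerate(shape)
        if s == 1 and t.data.shape[i + extra] != 1
    )
    out = _sum(t, axes, False) if axes else t
    return _reshape(out, shape)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def _add(a: Tensor, b: Tensor) -> Tensor:
    return _node(
        a.data + b.data,
        (a, b),
        (
            lambda ct: _sum_to_shape(ct, a.data.shape),
            lambda ct: _sum_to_shape(ct, b.data.shape),
        ),
    )


def _mul(a: Tensor, b: Tensor) -> Tensor:
    return _node(
        a.data * b.data,
        (a, b),
        (
            lambda ct: _sum_to_shape(ct * b, a.data.shape),
            lambda ct: _sum_to_shape(ct * a, b.data.shape),
        ),
    )


def _pow(a: Tensor, p: float) -> Tensor:
    return _node(
        a.data ** p,
        (a,),
        (lambda ct: ct * (_pow(a, p - 1.0) * p),),
    )


def _matmul(a: Tensor, b: Tensor) -> Tensor:
    if a.data.ndim != 2 or b.data.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    return _node(
        a.data @ b.data,
        (a, b),
        (
            lambda ct: ct @ _transpose(b),
            lambda ct: _transpose(a) @ ct,
        ),
    )


def _transpose(a: Tensor) -> Tensor:
    return _node(a.data.T, (a,), (lambda ct: _transpose(ct),))


def _reshape(a: Tensor, shape: tuple) -> Tensor:
    old = a.data.shape
    return _node(a.data.reshape(shape), (a,), (lambda ct: _reshape(ct, old),))


def _sum(a: Tensor, axis, keepdims: bool) -> Tensor:
    out = a.data.sum(axis=axis, keepdims=keepdims)
    shape = a.data.shape

    def vjp(ct: Tensor) -> Tensor:
        if axis is None:
            kshape = (1,) * len(shape)
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(a_ % len(shape) for a_ in axes)
            kshape = tuple(1 if i in axes else s for i, s in enumerate(shape))
        ct_k = ct if keepdims else _reshape(ct, kshape)
        return ct_k * Tensor(np.ones(shape))

    return _node(out, (a,), (vjp,))


def _tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)
    out = _node(out_data, (a,), ())
    if out.requires_grad:
        out._vjps = (lambda ct: ct * (1.0 - out * out),)
    return out


def _sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))
    out = _node(out_data, (a,), ())
    if out.requires_grad:
        out._vjps = (lambda ct: ct * out * (1.0 - out),)
    return out


def _log(a: Tensor) -> Tensor:
    return _node(np.log(a.data), (a,), (lambda ct: ct * _pow(a, -1.0),))


def _leaky_relu(a: Tensor, slope: float) -> Tensor:
    mask = np.where(a.data > 0.0, 1.0, slope)
    return _node(
        np.where(a.data > 0.0, a.data, slope * a.data),
        (a,),
        (lambda ct: ct * Tensor(mask),),
    )


def _clip_op(a: Tensor, bound: float, fn, pass_cmp) -> Tensor:
    mask = pass_cmp(a.data, bound).astype(np.float64)
    return _node(fn(a.data, bound), (a,), (lambda ct: ct * Tensor(mask),))


def _slice(a: Tensor, key) -> Tensor:
    shape = a.data.shape
    return _node(a.data[key], (a,), (lambda ct: _scatter(ct, shape, key),))


def _scatter(ct: Tensor, shape: tuple, key) -> Tensor:
    out = np.zeros(shape)
    out[key] = ct.data
    return _node(out, (ct,), (lambda c2: _slice(c2, key),))


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + [t.data.shape[axis] for t in tensors])

    def make_vjp(i):
        lo, hi = offsets[i], offsets[i + 1]

        def vjp(ct):
            key = tuple(
                slice(lo, hi) if ax == axis % ct.data.ndim else slice(None)
                for ax in range(ct.data.ndim)
            )
            return _slice(ct, key)

        return vjp

    return _node(data, tuple(tensors), tuple(make_vjp(i) for i in range(len(tensors))))


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------

def _topo_order(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order


def grad(output: Tensor, inputs: Sequence[Tensor]) -> list[Tensor]:
    """Gradients of a scalar output with respect to ``inputs``.

    The returned gradients are themselves graph tensors, so they can be
    differentiated again (double backprop).
    """
    if output.data.size != 1:
        raise ValueError("grad() expects a scalar output")
    topo = _topo_order(output)
    cot: dict[int, Tensor] = {id(output): Tensor(np.ones_like(output.data))}
    for node in reversed(topo):
        ct = cot.get(id(node))
        if ct is None:
            continue
        for parent, vjp in zip(node._parents, node._vjps):
            if not parent.requires_grad:
                continue
            g = vjp(ct)
            prev = cot.get(id(parent))
            cot[id(parent)] = g if prev is None else prev + g
    out = []
    for t in inputs:
        g = cot.get(id(t))
        out.append(g if g is not None else Tensor(np.zeros_like(t.data)))
    return out


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Linear:
    """Fully connected layer, He-initialized for leaky-ReLU stacks."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return [self.weight, self.bias]

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def infer(self, x: np.ndarray) -> np.ndarray:
        return x @ self.weight.data + self.bias.data


class BatchNorm1d:
    """Batch normalization over the batch axis.

    Training mode normalizes with batch statistics (differentiable); running
    statistics are tracked for inference, where they are treated as constants.
    """

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n), requires_grad=True)
        self.beta = Tensor(np.zeros(n), requires_grad=True)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    @property
    def params(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, train: bool = True) -> Tensor:
        if train:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) * Tensor(
                1.0 / np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta

    def infer(self, x: np.ndarray) -> np.ndarray:
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xhat * self.gamma.data + self.beta.data


class Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def __call__(self, x: Tensor, rng: np.random.Generator, train: bool = True) -> Tensor:
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.data.shape) < keep) / keep
        return x * Tensor(mask)

    def infer(self, x: np.ndarray) -> np.ndarray:
        return x


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.5, 0.9),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads: Sequence[Tensor]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(self.params, grads)):
            gd = g.data if isinstance(g, Tensor) else g
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * gd
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * gd * gd
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
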