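"""A compact reverse-mode automatic-differentiation core on numpy arrays.

Provides exactly what the attention-MIL scorer needs to train on a CPU:
tensors with broadcasting-aware gradients, dense and 2-D convolution layers
(im2col), batch normalisation with running statistics, the mish activation,
softmax/cross-entropy, and an Adam optimiser. Float64 throughout, so the
finite-difference gradient checks in the test suite hold to tight tolerance.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[Array] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[Array], None]] = None
        self._parents: tuple["Tensor", ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data: Array, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))

        return self._make(self.data ** exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full(self.shape, g))
            else:
                g_ = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g_, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))

        return self._make(self.data.reshape(*shape), (self,), backward)

    @property
    def T(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g.T)

        return self._make(self.data.T, (self,), backward)

    # -- pointwise nonlinearities ----------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), backward)

    def softplus(self):
        # log(1 + e^x), computed stably
        out_data = np.logaddexp(0.0, self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / (1.0 + np.exp(-self.data)))

        return self._make(out_data, (self,), backward)

    def mish(self):
        """x * tanh(softplus(x)) — the activation used in the MIL heads."""
        return self * self.softplus().tanh()

    # -- autograd driver --------------------------------------------------------
    def _accum(self, g: Array) -> None:
        if self.grad is None:
            self.grad = np.zeros(self.shape, dtype=np.float64)
        self.grad += g

    def backward(self, grad: Optional[Array] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order over the computation graph
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self._accum(grad)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))  # constant shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, labels: Array) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under ``logits``."""
    n, k = logits.shape
    logp = log_softmax(logits, axis=1)
    onehot = np.zeros((n, k))
    onehot[np.arange(n), np.asarray(labels, dtype=int)] = 1.0
    return -(logp * Tensor(onehot)).sum() * (1.0 / n)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in self.__dict__.values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def set_training(self, training: bool) -> None:
        for mod in self.modules():
            if isinstance(mod, BatchNorm1d):
                mod.training = training

    def state_arrays(self) -> dict[str, Array]:
        """Flat name -> array mapping of parameters and batch-norm statistics."""
        state: dict[str, Array] = {}

        def visit(mod: Module, prefix: str) -> None:
            for name, value in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(value, Tensor):
                    state[key] = value.data
                elif isinstance(value, np.ndarray):
                    state[key] = value
                elif isinstance(value, Module):
                    visit(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            visit(item, f"{key}.{i}.")

        visit(self, "")
        return state

    def load_state_arrays(self, state: dict[str, Array]) -> None:
        own = self.state_arrays()
        missing = set(own) - set(state)
        if missing:
            raise ValueError(f"missing state entries: {sorted(missing)}")

        def visit(mod: Module, prefix: str) -> None:
            for name, value in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(value, Tensor):
                    value.data = np.asarray(state[key], dtype=np.float64).reshape(value.shape)
                elif isinstance(value, np.ndarray):
                    setattr(mod, name, np.asarray(state[key], dtype=np.float64).reshape(value.shape))
                elif isinstance(value, Module):
                    visit(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            visit(item, f"{key}.{i}.")

        visit(self, "")


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm1d(Module):
    """Batch normalisation over the first axis with running statistics."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=0, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * x.data.mean(axis=0)
            )
            n = max(x.shape[0], 2)
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * x.data.var(axis=0) * n / (n - 1)
            )
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            mu = Tensor(self.running_mean)
            sd = Tensor(np.sqrt(self.running_var + self.eps))
            xhat = (x - mu) / sd
        return xhat * self.gamma + self.beta


def _im2col(x: Array, k: int, stride: int) -> tuple[Array, int, int]:
    """(N, C, H, W) -> (N, OH, OW, C*k*k) view-based patch matrix."""
    n, c, h, w = x.shape
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, oh, ow, k, k),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
        writeable=False,
    )
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh, ow, c * k * k)
    return np.ascontiguousarray(cols), oh, ow


class Conv2d(Module):
    """Valid-padding 2-D convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng: np.random.Generator):
        fan_in = c_in * kernel * kernel
        scale = math.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.kernel = kernel
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        k, stride = self.kernel, self.stride
        weight, bias = self.weight, self.bias
        n, c_in = x.shape[0], x.shape[1]
        cols, oh, ow = _im2col(x.data, k, stride)
        wmat = weight.data.reshape(weight.shape[0], -1)  # (C_out, C_in*k*k)
        out_data = cols @ wmat.T + bias.data  # (N, OH, OW, C_out)
        out_data = out_data.transpose(0, 3, 1, 2)

        def backward(g):
            gmat = g.transpose(0, 2, 3, 1).reshape(-1, weight.shape[0])  # (N*OH*OW, C_out)
            cols2 = cols.reshape(-1, cols.shape[-1])
            if weight.requires_grad:
                weight._accum((gmat.T @ cols2).reshape(weight.shape))
            if bias.requires_grad:
                bias._accum(gmat.sum(axis=0))
            if x.requires_grad:
                dcols = (gmat @ wmat).reshape(n, oh, ow, c_in, k, k)
                dx = np.zeros(x.shape, dtype=np.float64)
                for i in range(k):
                    for j in range(k):
                        dx[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride] += (
                            dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                        )
                x._accum(dx)

        return x._make(out_data, (x, weight, bias), backward)


class Adam:
    """Adam optimiser with the standard bias correction."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros(p.shape) for p in self.params]
        self.v = [np.zeros(p.shape) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
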