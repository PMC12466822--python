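"""Minimal reverse-mode autodiff and neural-network building blocks on numpy.

This module provides exactly the operations the package's networks need:
dense layers, 2-D convolution (im2col), batch normalisation, GELU / ReLU /
sigmoid activations, nearest-neighbour up-sampling, 2x2 average pooling,
channel concatenation and elementwise arithmetic with broadcasting.  It is
deliberately small: networks here are tiny (tens of thousands of
parameters) and run on a single CPU, so clarity and correctness win over
throughput.

Gradients are accumulated by a tape-free topological backward pass over the
graph recorded during the forward computation (the classic micrograd
pattern, generalised to ndarrays).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Tensor",
    "Module",
    "Conv2d",
    "Linear",
    "BatchNorm2d",
    "Adam",
    "gelu_array",
]

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()

    # -- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _init_grad(self):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)

    def backward(self, grad: np.ndarray | None = None):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._init_grad()
        self.grad += np.ones_like(self.data) if grad is None else grad
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward()

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad or p._prev for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward():
            for t in (self, other):
                t._init_grad()
            self.grad += _unbroadcast(out.grad, self.data.shape)
            other.grad += _unbroadcast(out.grad, other.data.shape)

        out = self._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward():
            for t in (self, other):
                t._init_grad()
            self.grad += _unbroadcast(out.grad * other.data, self.data.shape)
            other.grad += _unbroadcast(out.grad * self.data, other.data.shape)

        out = self._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** (-1.0)

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward():
            self._init_grad()
            self.grad += out.grad * p * self.data ** (p - 1.0)

        out = self._make(out_data, (self,), backward)
        return out

    def matmul(self, other: "Tensor"):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward():
            for t in (self, other):
                t._init_grad()
            self.grad += out.grad @ np.swapaxes(other.data, -1, -2)
            other.grad += np.swapaxes(self.data, -1, -2) @ out.grad

        out = self._make(out_data, (self, other), backward)
        return out

    __matmul__ = matmul

    # -- reductions / reshaping ----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            self._init_grad()
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self.grad += np.broadcast_to(g, self.data.shape)

        out = self._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)

        def backward():
            self._init_grad()
            self.grad += out.grad.reshape(self.data.shape)

        out = self._make(out_data, (self,), backward)
        return out

    def transpose(self, axes):
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward():
            self._init_grad()
            self.grad += out.grad.transpose(inv)

        out = self._make(out_data, (self,), backward)
        return out

    # -- nonlinearities -------------------------------------------------
    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward():
            self._init_grad()
            self.grad += out.grad * (self.data > 0.0)

        out = self._make(out_data, (self,), backward)
        return out

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward():
            self._init_grad()
            self.grad += out.grad * out_data * (1.0 - out_data)

        out = self._make(out_data, (self,), backward)
        return out

    def gelu(self):
        """tanh-approximation GELU: 0.5*x*(1 + tanh(sqrt(2/pi)*(x + 0.044715*x^3)))."""
        x = self.data
        inner = _SQRT_2_OVER_PI * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def backward():
            self._init_grad()
            dinner = _SQRT_2_OVER_PI * (1.0 + 3 * 0.044715 * x**2)
            grad = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner
            self.grad += out.grad * grad

        out = self._make(out_data, (self,), backward)
        return out

    def log(self):
        out_data = np.log(self.data)

        def backward():
            self._init_grad()
            self.grad += out.grad / self.data

        out = self._make(out_data, (self,), backward)
        return out

    # -- spatial ops (NCHW) ---------------------------------------------
    def avg_pool2x2(self):
        b, c, h, w = self.data.shape
        if h % 2 or w % 2:
            raise ValueError(f"avg_pool2x2 needs even spatial dims, got {h}x{w}")
        out_data = self.data.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

        def backward():
            self._init_grad()
            g = out.grad[:, :, :, None, :, None] / 4.0
            self.grad += np.broadcast_to(g, (b, c, h // 2, 2, w // 2, 2)).reshape(
                b, c, h, w
            )

        out = self._make(out_data, (self,), backward)
        return out

    def upsample_nearest2(self):
        b, c, h, w = self.data.shape
        out_data = np.repeat(np.repeat(self.data, 2, axis=2), 2, axis=3)

        def backward():
            self._init_grad()
            self.grad += out.grad.reshape(b, c, h, 2, w, 2).sum(axis=(3, 5))

        out = self._make(out_data, (self,), backward)
        return out

    def global_avg_pool(self):
        """Mean over spatial dims of an NCHW tensor, keepdims."""
        return self.mean(axis=(2, 3), keepdims=True)


def concat(tensors: list, axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            t._init_grad()
            idx = [slice(None)] * out_data.ndim
            idx[axis] = slice(lo, hi)
            t.grad += out.grad[tuple(idx)]

    out = tensors[0]._make(out_data, tuple(tensors), backward)
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution on NCHW input via im2col.  weight: (Cout, Cin, k, k)."""
    b, cin, h, w = x.data.shape
    cout, cin_w, k, _ = weight.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        if pad
        else x.data
    )
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    col = np.empty((b, cin * k * k, ho * wo))
    for ki in range(k):
        for kj in range(k):
            patch = xp[:, :, ki : ki + ho * stride : stride, kj : kj + wo * stride : stride]
            col[:, (ki * k + kj) :: k * k, :] = patch.reshape(b, cin, ho * wo)
    wflat = weight.data.reshape(cout, cin * k * k)
    out_data = (wflat @ col).reshape(b, cout, ho, wo)
    if bias is not None:
        out_data += bias.data[None, :, None, None]

    def backward():
        x._init_grad()
        weight._init_grad()
        g = out.grad.reshape(b, cout, ho * wo)
        weight.grad += np.tensordot(g, col, axes=([0, 2], [0, 2])).reshape(
            cout, cin, k, k
        )
        if bias is not None:
            bias._init_grad()
            bias.grad += out.grad.sum(axis=(0, 2, 3))
        dcol = np.tensordot(g, wflat, axes=([1], [0])).transpose(0, 2, 1)
        dxp = np.zeros_like(xp)
        for ki in range(k):
            for kj in range(k):
                patch = dcol[:, (ki * k + kj) :: k * k, :].reshape(b, cin, ho, wo)
                dxp[:, :, ki : ki + ho * stride : stride, kj : kj + wo * stride : stride] += patch
        x.grad += dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp

    parents = (x, weight) if bias is None else (x, weight, bias)
    out = x._make(out_data, parents, backward)
    return out


def logistic_bce(logits: Tensor, targets: np.ndarray, weights: np.ndarray | None = None) -> Tensor:
    """Numerically stable binary cross-entropy on logits.

    forward: mean of w * (softplus(z) - z*t); backward: w * (sigmoid(z) - t) / n.
    """
    t = np.asarray(targets, dtype=float)
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    z = logits.data
    loss = w * (np.logaddexp(0.0, z) - z * t)
    out_data = loss.mean()

    def backward():
        logits._init_grad()
        p = 1.0 / (1.0 + np.exp(-z))
        logits.grad += out.grad * w * (p - t) / t.size

    out = logits._make(out_data, (logits,), backward)
    return out


def gelu_array(x: np.ndarray) -> np.ndarray:
    """Plain-ndarray tanh-approximation GELU (no graph)."""
    x = np.asarray(x, dtype=float)
    return 0.5 * x * (1.0 + np.tanh(_SQRT_2_OVER_PI * (x + 0.044715 * x**3)))


# ---------------------------------------------------------------------------
# Modules


class Module:
    """Base class: recursive parameter collection and train/eval switching."""

    def parameters(self) -> list:
        params = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def set_training(self, mode: bool):
        for v in vars(self).values():
            if isinstance(v, Module):
                v.set_training(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.set_training(mode)
        if hasattr(self, "training"):
            self.training = mode
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> dict:
        """Flat name -> ndarray mapping of parameters and buffers."""
        out = {}

        def walk(obj, prefix):
            for name, v in vars(obj).items():
                key = f"{prefix}{name}"
                if isinstance(v, Tensor):
                    out[key] = v.data
                elif isinstance(v, np.ndarray):
                    out[key] = v
                elif isinstance(v, Module):
                    walk(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")
                        elif isinstance(item, Tensor):
                            out[f"{key}.{i}"] = item.data
        walk(self, "")
        return out

    def load_state_arrays(self, state: dict):
        for key, arr in self.state_arrays().items():
            if key not in state:
                raise KeyError(f"missing parameter {key!r} in checkpoint")
            arr[...] = state[key]
        return self


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        scale = math.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, scale, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int | None = None,
        bias: bool = True,
    ):
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad
        scale = math.sqrt(2.0 / (c_in * k * k))
        self.weight = Tensor(rng.normal(0.0, scale, (c_out, c_in, k, k)), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    """Per-channel batch normalisation (batch stats in train mode, running
    stats in eval mode)."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centred = x - mu
            var = (centred**2.0).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.data.reshape(-1)
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var.data.reshape(-1)
            )
            xhat = centred * (var + self.eps) ** (-0.5)
        else:
            mu = self.running_mean[None, :, None, None]
            var = self.running_var[None, :, None, None]
            xhat = (x - mu) * Tensor((var + self.eps) ** (-0.5))
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params: list, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
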