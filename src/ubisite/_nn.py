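"""Minimal feed-forward neural-network core on numpy.

Implements exactly the building blocks the site-prediction models need:
fully-connected layers, batch normalization, Leaky ReLU, residual blocks
with the identity-vs-affine skip rule, and the AdamW optimizer (Adam with
decoupled weight decay).  Forward passes cache what the hand-written
backward passes need; ``input_gradient`` backpropagates all the way to the
input, which is what integrated-gradients attribution consumes.

Everything is deterministic given the ``numpy.random.Generator`` used at
construction; there is no hidden global state.
"""

from __future__ import annotations

import struct

import numpy as np

LEAKY_SLOPE = 0.01
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


class Parameter:
    """A learnable array with its accumulated gradient.

    ``decay`` marks whether AdamW's decoupled weight decay applies
    (weights yes; biases and batch-norm scale/shift no, the common
    convention).
    """

    __slots__ = ("value", "grad", "decay", "name")

    def __init__(self, value: np.ndarray, decay: bool, name: str) -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.decay = decay
        self.name = name


class Layer:
    """Base class: forward caches, backward consumes the cache."""

    def parameters(self) -> list[Parameter]:
        return []

    def buffers(self) -> list[tuple[str, "BatchNorm"]]:
        """Named non-learnable state (batch-norm running statistics)."""
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 name: str = "linear") -> None:
        # He initialisation, appropriate for the leaky-ReLU stacks used here
        scale = np.sqrt(2.0 / in_dim)
        self.W = Parameter(rng.normal(0.0, scale, size=(in_dim, out_dim)),
                           decay=True, name=f"{name}.W")
        self.b = Parameter(np.zeros(out_dim), decay=False, name=f"{name}.b")
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad_out
        self.b.grad += grad_out.sum(axis=0)
        return grad_out @ self.W.value.T


class BatchNorm(Layer):
    """1-d batch normalization with running statistics for inference."""

    def __init__(self, dim: int, name: str = "bn") -> None:
        self.name = name
        self.gamma = Parameter(np.ones(dim), decay=False, name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(dim), decay=False, name=f"{name}.beta")
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def buffers(self) -> list[tuple[str, "BatchNorm"]]:
        return [(self.name, self)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = ((1 - _BN_MOMENTUM) * self.running_mean
                                 + _BN_MOMENTUM * mean)
            # unbiased running variance, matching the usual convention
            n = x.shape[0]
            unbiased = var * n / max(n - 1, 1)
            self.running_var = ((1 - _BN_MOMENTUM) * self.running_var
                                + _BN_MOMENTUM * unbiased)
        else:
            mean = self.running_mean
            var = self.running_var
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        x_hat = (x - mean) * inv_std
        self._cache = (x_hat, inv_std, train, x.shape[0])
        return self.gamma.value * x_hat + self.beta.value

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x_hat, inv_std, train, n = self._cache
        self.gamma.grad += (grad_out * x_hat).sum(axis=0)
        self.beta.grad += grad_out.sum(axis=0)
        g = grad_out * self.gamma.value
        if not train:
            return g * inv_std
        # standard batch-norm backward through the batch statistics
        return (inv_std / n) * (n * g - g.sum(axis=0)
                                - x_hat * (g * x_hat).sum(axis=0))


class LeakyReLU(Layer):
    def __init__(self, slope: float = LEAKY_SLOPE) -> None:
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad_out, self.slope * grad_out)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def buffers(self) -> list[tuple[str, "BatchNorm"]]:
        return [b for layer in self.layers for b in layer.buffers()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out


class Identity(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out


class ResBlock(Layer):
    """Two FC layers (in->out, out->out), each batch-norm + leaky ReLU.

    The skip path is an identity mapping when the dimensions match and a
    single affine map (no activation) otherwise.
    """

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 name: str = "res") -> None:
        self.main = Sequential([
            Linear(in_dim, out_dim, rng, name=f"{name}.fc1"),
            BatchNorm(out_dim, name=f"{name}.bn1"),
            LeakyReLU(),
            Linear(out_dim, out_dim, rng, name=f"{name}.fc2"),
            BatchNorm(out_dim, name=f"{name}.bn2"),
            LeakyReLU(),
        ])
        if in_dim == out_dim:
            self.skip: Layer = Identity()
        else:
            self.skip = Linear(in_dim, out_dim, rng, name=f"{name}.skip")

    def parameters(self) -> list[Parameter]:
        return self.main.parameters() + self.skip.parameters()

    def buffers(self) -> list[tuple[str, "BatchNorm"]]:
        return self.main.buffers() + self.skip.buffers()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return self.main.forward(x, train) + self.skip.forward(x, train)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return self.main.backward(grad_out) + self.skip.backward(grad_out)


def dense_stack(in_dim: int, hidden_dims: list[int], rng: np.random.Generator,
                name: str = "dense") -> tuple[Sequential, int]:
    """Affine + batch-norm + leaky-ReLU stack; returns (stack, last width)."""
    layers: list[Layer] = []
    prev = in_dim
    for i, width in enumerate(hidden_dims):
        layers += [Linear(prev, width, rng, name=f"{name}.{i}"),
                   BatchNorm(width, name=f"{name}.{i}.bn"),
                   LeakyReLU()]
        prev = width
    return Sequential(layers), prev


def res_stack(in_dim: int, widths: list[int], num_blocks: int,
              rng: np.random.Generator, name: str = "res") -> tuple[Sequential, int]:
    """``num_blocks`` residual blocks whose widths cycle through ``widths``."""
    layers: list[Layer] = []
    prev = in_dim
    for i in range(num_blocks):
        width = widths[i % len(widths)]
        layers.append(ResBlock(prev, width, rng, name=f"{name}.{i}"))
        prev = width
    return Sequential(layers), prev


class AdamW:
    """Adam with decoupled weight decay (applied only to ``decay`` params)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 weight_decay: float = 8e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            update = (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            if p.decay:
                p.value -= self.lr * self.weight_decay * p.value
            p.value -= self.lr * update


def softplus(x: np.ndarray) -> np.ndarray:
    """log(1 + exp(x)) computed without overflow."""
    return np.logaddexp(0.0, x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


_PARAMS_MAGIC = b"UBIPAR01"


def save_arrays(path, arrays: dict[str, np.ndarray]) -> None:
    """Write named float64 arrays to a deterministic binary container.

    Unlike zip-based formats the byte stream depends only on the data
    (names sorted, little-endian, no timestamps), so identical models
    always produce identical checkpoint files.
    """
    with open(path, "wb") as fh:
        fh.write(_PARAMS_MAGIC)
        fh.write(struct.pack("<I", len(arrays)))
        for name in sorted(arrays):
            arr = np.ascontiguousarray(arrays[name], dtype="<f8")
            nb = name.encode()
            fh.write(struct.pack("<I", len(nb)))
            fh.write(nb)
            fh.write(struct.pack("<I", arr.ndim))
            fh.write(struct.pack(f"<{arr.ndim}Q", *arr.shape))
            fh.write(arr.tobytes())


def load_arrays(path) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    with open(path, "rb") as fh:
        if fh.read(len(_PARAMS_MAGIC)) != _PARAMS_MAGIC:
            raise ValueError(f"{path}: not a parameter container (bad magic)")
        (count,) = struct.unpack("<I", fh.read(4))
        for _ in range(count):
            (name_len,) = struct.unpack("<I", fh.read(4))
            name = fh.read(name_len).decode()
            (ndim,) = struct.unpack("<I", fh.read(4))
            shape = struct.unpack(f"<{ndim}Q", fh.read(8 * ndim))
            n_items = int(np.prod(shape)) if ndim else 1
            data = np.frombuffer(fh.read(8 * n_items), dtype="<f8")
            out[name] = data.reshape(shape).astype(np.float64)
    return out


def state_dict(modules: list[Layer]) -> dict[str, np.ndarray]:
    """Flat name -> array mapping of all parameters and running statistics."""
    state: dict[str, np.ndarray] = {}
    for mod in modules:
        for p in mod.parameters():
            if p.name in state:
                raise ValueError(f"duplicate parameter name {p.name!r}")
            state[p.name] = p.value
        for name, bn in mod.buffers():
            state[f"{name}.running_mean"] = bn.running_mean
            state[f"{name}.running_var"] = bn.running_var
    return state


def load_state(modules: list[Layer], state: dict[str, np.ndarray]) -> None:
    for mod in modules:
        for p in mod.parameters():
            if p.name not in state:
                raise KeyError(f"missing parameter {p.name!r} in checkpoint")
            arr = np.asarray(state[p.name], dtype=np.float64)
            if arr.shape != p.value.shape:
                raise ValueError(f"shape mismatch for {p.name!r}: "
                                 f"expected {p.value.shape}, got {arr.shape}")
            p.value = arr
        for name, bn in mod.buffers():
            bn.running_mean = np.asarray(state[f"{name}.running_mean"],
                                         dtype=np.float64)
            bn.running_var = np.asarray(state[f"{name}.running_var"],
                                        dtype=np.float64)
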