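"""Computational layers of the mesh CNN: convolution, mean pooling with its
error-distribution backward rule, batch normalization and ReLU.

Mesh convolution is the bilinear form O = I x W: the filter point matrix I
(nodes x points x channels, built by :mod:`spherecnn.patch_sampling`)
multiplied by per-filter weight vectors. Mean pooling averages each coarse
node's fine-level children (its own value plus its 1-ring); backpropagation
distributes the coarse error equally over those children — implemented as
the exact adjoint of the forward averaging, so gradient checks are exact.

Two surfaces are provided:

* functional ops (`mesh_conv_forward`, `mesh_pool_backward`, ...) mirroring
  the mathematical definitions, convenient for oracles and unit tests;
* stateful `Layer` objects with a batch dimension, caching, parameter
  storage and freezing, used to assemble trainable networks.

All gradients are written by hand; no autodiff framework is involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .icosphere import PoolingMap
from .patch_sampling import FilterPointMatrix, SamplingMap

__all__ = [
    "ConvFilterBank",
    "mesh_conv_forward",
    "mesh_conv_backward",
    "mesh_pool_forward",
    "mesh_pool_backward",
    "relu",
    "Layer",
    "MeshConvLayer",
    "MeshPoolLayer",
    "BatchNormLayer",
    "ReLULayer",
    "FlattenLayer",
    "DenseLayer",
    "SoftmaxCrossEntropy",
    "Sequential",
    "SGD",
]


# ---------------------------------------------------------------------------
# functional operations
# ---------------------------------------------------------------------------


@dataclass
class ConvFilterBank:
    """Fb filter weight vectors, each of length P * C_in, plus biases."""

    weights: np.ndarray  # (Fb, P*C_in)
    bias: np.ndarray  # (Fb,)

    @property
    def n_filters(self) -> int:
        return self.weights.shape[0]


def _as_ipc(I) -> tuple[np.ndarray, SamplingMap | None]:
    if isinstance(I, FilterPointMatrix):
        return I.values, I.provenance
    return np.asarray(I, dtype=np.float64), None


def mesh_conv_forward(I, bank: ConvFilterBank) -> np.ndarray:
    """O[n, f] = sum_{p,c} I[n,p,c] W_f[p,c] + b_f; returns (N, Fb)."""
    v, _ = _as_ipc(I)
    n, p, c = v.shape
    if bank.weights.shape[1] != p * c:
        raise ValueError(
            f"filter length {bank.weights.shape[1]} != points*channels {p * c}"
        )
    return v.reshape(n, p * c) @ bank.weights.T + bank.bias


def mesh_conv_backward(
    grad_out: np.ndarray, I, bank: ConvFilterBank
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact gradients of the forward bilinear form.

    Returns (grad_I, grad_W, grad_bias). Gradient entries at padded
    (sentinel) filter points are zeroed: the sentinel is a constant 0, not a
    variable.
    """
    v, smap = _as_ipc(I)
    n, p, c = v.shape
    g = np.asarray(grad_out, dtype=np.float64)
    if g.shape != (n, bank.n_filters):
        raise ValueError(f"grad_out shape {g.shape} != {(n, bank.n_filters)}")
    grad_flat = g @ bank.weights  # (N, P*C)
    grad_I = grad_flat.reshape(n, p, c)
    if smap is not None and smap.has_padding:
        grad_I = grad_I * (smap.index != smap.sentinel)[:, :, None]
    grad_W = g.T @ v.reshape(n, p * c)
    grad_bias = g.sum(axis=0)
    return grad_I, grad_W, grad_bias


def mesh_pool_forward(x: np.ndarray, pm: PoolingMap) -> np.ndarray:
    """Mean over each coarse node's children; feature count unchanged."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] != pm.n_fine:
        raise ValueError(f"input has {x.shape[0]} nodes, map expects {pm.n_fine}")
    return pm.matrix() @ x


def mesh_pool_backward(grad_coarse: np.ndarray, pm: PoolingMap) -> np.ndarray:
    """Equal distribution of the coarse error over children: the adjoint.

    grad_fine[j] = sum over parents c of j of grad_coarse[c] / |children(c)|.
    """
    g = np.asarray(grad_coarse, dtype=np.float64)
    if g.shape[0] != pm.n_coarse:
        raise ValueError(f"gradient has {g.shape[0]} nodes, map expects {pm.n_coarse}")
    return pm.matrix().T @ g


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


# ---------------------------------------------------------------------------
# stateful layers (batched)
# ---------------------------------------------------------------------------


class Layer:
    """Base class: parameter dict, gradient dict, freeze flag.

    ``forward`` consumes a batch-first array and caches what ``backward``
    needs; frozen layers skip parameter-gradient computation and, for batch
    normalization, always use running statistics.
    """

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.frozen = False

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


def _fan_in_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


class MeshConvLayer(Layer):
    """Mesh convolution over a fixed sampling map.

    Input (B, N, C_in) -> gather to (B, N, P*C_in) -> multiply by the weight
    matrix (P*C_in, F). The backward pass scatter-adds the filter-point
    gradient back onto surface nodes through a precomputed sparse matrix;
    sentinel (padded) points route to a discarded row.
    """

    def __init__(
        self,
        smap: SamplingMap,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator,
        bias: bool = True,
    ) -> None:
        super().__init__()
        self.smap = smap
        self.in_channels = in_channels
        self.out_channels = out_channels
        p = smap.n_points
        self.params["W"] = _fan_in_uniform(
            rng, p * in_channels, (p * in_channels, out_channels)
        )
        self.use_bias = bias
        if bias:
            self.params["b"] = np.zeros(out_channels)
        n = smap.n_nodes
        cols = np.arange(n * p)
        self._scatter = sp.csr_matrix(
            (np.ones(n * p), (smap.index.ravel(), cols)), shape=(n + 1, n * p)
        )
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, n, c = x.shape
        if n != self.smap.n_nodes or c != self.in_channels:
            raise ValueError(
                f"expected input (B, {self.smap.n_nodes}, {self.in_channels}), got {x.shape}"
            )
        padded = np.concatenate([x, np.zeros((b, 1, c))], axis=1)
        xp = padded[:, self.smap.index, :].reshape(b, n, -1)  # (B, N, P*C)
        self._cache = (xp, b, n, c)
        out = xp @ self.params["W"]
        if self.use_bias:
            out += self.params["b"]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp, b, n, c = self._cache
        if not self.frozen:
            self.grads["W"] = np.einsum("bnk,bnf->kf", xp, grad)
            if self.use_bias:
                self.grads["b"] = grad.sum(axis=(0, 1))
        g_pts = grad @ self.params["W"].T  # (B, N, P*C)
        p = self.smap.n_points
        # (B, N*P, C) -> (N*P, B*C) for one sparse scatter
        g_pts = g_pts.reshape(b, n * p, c).transpose(1, 0, 2).reshape(n * p, b * c)
        g_nodes = self._scatter @ g_pts  # (N+1, B*C); last row = sentinel
        return g_nodes[:-1].reshape(n, b, c).transpose(1, 0, 2)


class MeshPoolLayer(Layer):
    """Mean (default) or max pooling from one icosphere level to its parent."""

    def __init__(self, pm: PoolingMap, mode: str = "mean") -> None:
        super().__init__()
        if mode not in ("mean", "max"):
            raise ValueError(f"unknown pooling mode {mode!r}")
        self.pm = pm
        self.mode = mode
        self._A = pm.matrix()
        if mode == "max":
            k = max(len(ch) for ch in pm.children)
            idx = np.full((pm.n_coarse, k), pm.n_fine, dtype=np.int64)
            for c, ch in enumerate(pm.children):
                idx[c, : len(ch)] = ch
            self._max_idx = idx
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, n, f = x.shape
        if n != self.pm.n_fine:
            raise ValueError(f"expected {self.pm.n_fine} nodes, got {n}")
        if self.mode == "mean":
            self._cache = (b, f)
            xt = x.transpose(1, 0, 2).reshape(n, b * f)
            out = self._A @ xt
            return out.reshape(self.pm.n_coarse, b, f).transpose(1, 0, 2)
        padded = np.concatenate([x, np.full((b, 1, f), -np.inf)], axis=1)
        gathered = padded[:, self._max_idx, :]  # (B, Nc, K, F)
        arg = gathered.argmax(axis=2)
        self._cache = (b, f, arg)
        return np.take_along_axis(gathered, arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.mode == "mean":
            b, f = self._cache
            gt = grad.transpose(1, 0, 2).reshape(self.pm.n_coarse, b * f)
            out = self._A.T @ gt
            return out.reshape(self.pm.n_fine, b, f).transpose(1, 0, 2)
        b, f, arg = self._cache
        src = self._max_idx[None, :, :].repeat(b, axis=0)  # (B, Nc, K)
        winners = np.take_along_axis(src[:, :, :, None].repeat(f, 3), arg[:, :, None, :], axis=2)[:, :, 0, :]
        out = np.zeros((b, self.pm.n_fine + 1, f))
        bi = np.arange(b)[:, None, None]
        fi = np.arange(f)[None, None, :]
        np.add.at(out, (bi, winners, fi), grad)
        return out[:, :-1, :]


class BatchNormLayer(Layer):
    """Per-feature normalization over all leading axes (batch and nodes).

    Training mode uses batch statistics and updates exponential running
    statistics; inference (and frozen) mode normalizes with the stored
    running statistics, making it deterministic.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(n_features)
        self.params["beta"] = np.zeros(n_features)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train and not self.frozen:
            m = int(np.prod(x.shape[:-1]))
            if m < 2:
                raise ValueError("batch normalization needs >= 2 samples in training mode")
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var * m / max(m - 1, 1)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, axes, train and not self.frozen)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes, batch_mode = self._cache
        if not self.frozen:
            self.grads["gamma"] = (grad * xhat).sum(axis=axes)
            self.grads["beta"] = grad.sum(axis=axes)
        gxhat = grad * self.params["gamma"]
        if not batch_mode:
            return gxhat * inv_std
        m = np.prod([xhat.shape[a] for a in axes])
        return (
            inv_std
            / m
            * (
                m * gxhat
                - gxhat.sum(axis=axes)
                - xhat * (gxhat * xhat).sum(axis=axes)
            )
        )


class ReLULayer(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class FlattenLayer(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class DenseLayer(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = _fan_in_uniform(rng, n_in, (n_in, n_out))
        self.params["b"] = np.zeros(n_out)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if not self.frozen:
            self.grads["W"] = self._x.T @ grad
            self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class SoftmaxCrossEntropy:
    """Softmax output with cross-entropy loss; gradient w.r.t. logits."""

    def forward(self, logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        b = logits.shape[0]
        loss = -np.mean(np.log(probs[np.arange(b), labels] + 1e-300))
        self._cache = (probs, labels, b)
        return float(loss), probs

    def backward(self) -> np.ndarray:
        probs, labels, b = self._cache
        g = probs.copy()
        g[np.arange(b), labels] -= 1.0
        return g / b


class Sequential:
    """An ordered layer stack with shared forward/backward plumbing."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray, to_input: bool = False) -> np.ndarray | None:
        lowest = 0
        if not to_input:
            # no gradient is needed below the deepest trainable layer
            for i, layer in enumerate(self.layers):
                if not layer.frozen:
                    lowest = i
                    break
        for layer in reversed(self.layers[lowest:]):
            grad = layer.backward(grad)
        return grad if to_input else None

    def freeze(self, n_layers: int) -> None:
        if n_layers > len(self.layers):
            raise ValueError(
                f"cannot freeze {n_layers} of {len(self.layers)} layers"
            )
        for layer in self.layers[:n_layers]:
            layer.frozen = True

    def trainable(self):
        for layer in self.layers:
            if not layer.frozen:
                for name in layer.params:
                    yield layer, name

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, model: Sequential, momentum: float = 0.9, weight_decay: float = 0.0):
        self.model = model
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity: dict[tuple[int, str], np.ndarray] = {}

    def step(self, lr: float) -> None:
        for layer, name in self.model.trainable():
            if name not in layer.grads:
                continue
            g = layer.grads[name]
            if self.weight_decay:
                g = g + self.weight_decay * layer.params[name]
            key = (id(layer), name)
            v = self.velocity.get(key)
            v = g if v is None else self.momentum * v + g
            self.velocity[key] = v
            layer.params[name] -= lr * v
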