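"""Minimal feed-forward / convolutional network engine in numpy.

Implements exactly what the two neural classifiers need: dense layers,
full-height and 1-D convolutions, PReLU activations with a learnable slope,
inverted dropout, max-pooling, mean-squared-error loss against {0,1}
targets, and the RMSProp and Adagrad optimizers. Training is deterministic
given the seed. The scale (480 inputs, 64 kernels, batches of 128) keeps
plain numpy fast enough that no framework is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Dense",
    "PReLU",
    "Dropout",
    "FullHeightConv",
    "Conv1D",
    "MaxPool1D",
    "Flatten",
    "Network",
    "RMSProp",
    "Adagrad",
]


class Layer:
    """Base layer: forward/backward plus flat parameter and gradient lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator):
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        # He-style init, suited to rectifier activations
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad_out):
        self.grads[0][...] = self._x.T @ grad_out
        self.grads[1][...] = grad_out.sum(axis=0)
        return grad_out @ self.W.T


class PReLU(Layer):
    """Rectifier with a learnable negative-side slope (one slope per layer)."""

    def __init__(self, init_slope: float = 0.25) -> None:
        super().__init__()
        self.a = np.array([init_slope])
        self.params = [self.a]
        self.grads = [np.zeros_like(self.a)]

    def forward(self, x, training, rng):
        self._x = x
        return np.where(x > 0, x, self.a[0] * x)

    def backward(self, grad_out):
        neg = self._x <= 0
        self.grads[0][0] = np.sum(grad_out[neg] * self._x[neg])
        gx = grad_out.copy()
        gx[neg] *= self.a[0]
        return gx


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at prediction time."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad_out):
        return grad_out if self._mask is None else grad_out * self._mask


class FullHeightConv(Layer):
    """Convolution whose kernels span the full input height.

    Input (N, H, W_in); ``n_kernels`` kernels of shape (H, kw), stride 1,
    no padding; output (N, n_kernels, W_in - kw + 1). With H = 24 marks and
    kw = 2 this is the snapshot-consuming first layer: each kernel reads all
    marks over two adjacent bins.
    """

    def __init__(self, height: int, kw: int, n_kernels: int, rng) -> None:
        super().__init__()
        self.height, self.kw, self.n_kernels = height, kw, n_kernels
        fan_in = height * kw
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(n_kernels, fan_in))
        self.b = np.zeros(n_kernels)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _im2col(self, x):
        n, h, w = x.shape
        w_out = w - self.kw + 1
        cols = np.empty((n, w_out, h * self.kw))
        for j in range(w_out):
            cols[:, j, :] = x[:, :, j : j + self.kw].reshape(n, -1)
        return cols

    def forward(self, x, training, rng):
        if x.ndim != 3 or x.shape[1] != self.height:
            raise ValueError(f"expected (N, {self.height}, W) input, got {x.shape}")
        self._shape = x.shape
        self._cols = self._im2col(x)                      # (N, W_out, H*kw)
        out = self._cols @ self.W.T + self.b              # (N, W_out, K)
        return out.transpose(0, 2, 1)                     # (N, K, W_out)

    def backward(self, grad_out):
        g = grad_out.transpose(0, 2, 1)                   # (N, W_out, K)
        self.grads[0][...] = np.einsum("nwk,nwf->kf", g, self._cols)
        self.grads[1][...] = g.sum(axis=(0, 1))
        gcols = g @ self.W                                # (N, W_out, H*kw)
        n, h, w = self._shape
        gx = np.zeros(self._shape)
        w_out = w - self.kw + 1
        for j in range(w_out):
            gx[:, :, j : j + self.kw] += gcols[:, j, :].reshape(n, h, self.kw)
        return gx


class Conv1D(Layer):
    """1-D convolution over channel stacks: (N, C_in, W) -> (N, C_out, W-kw+1)."""

    def __init__(self, c_in: int, c_out: int, kw: int, rng) -> None:
        super().__init__()
        self.c_in, self.c_out, self.kw = c_in, c_out, kw
        fan_in = c_in * kw
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training, rng):
        if x.ndim != 3 or x.shape[1] != self.c_in:
            raise ValueError(f"expected (N, {self.c_in}, W) input, got {x.shape}")
        n, c, w = x.shape
        self._shape = x.shape
        w_out = w - self.kw + 1
        cols = np.empty((n, w_out, c * self.kw))
        for j in range(w_out):
            cols[:, j, :] = x[:, :, j : j + self.kw].reshape(n, -1)
        self._cols = cols
        out = cols @ self.W.T + self.b
        return out.transpose(0, 2, 1)

    def backward(self, grad_out):
        g = grad_out.transpose(0, 2, 1)
        self.grads[0][...] = np.einsum("nwk,nwf->kf", g, self._cols)
        self.grads[1][...] = g.sum(axis=(0, 1))
        gcols = g @ self.W
        n, c, w = self._shape
        gx = np.zeros(self._shape)
        w_out = w - self.kw + 1
        for j in range(w_out):
            gx[:, :, j : j + self.kw] += gcols[:, j, :].reshape(n, c, self.kw)
        return gx


class MaxPool1D(Layer):
    """Width-wise max pooling with pool size = stride; trailing remainder dropped."""

    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x, training, rng):
        n, c, w = x.shape
        w_out = w // self.pool
        xt = x[:, :, : w_out * self.pool].reshape(n, c, w_out, self.pool)
        self._argmax = xt.argmax(axis=3)
        self._shape = x.shape
        return xt.max(axis=3)

    def backward(self, grad_out):
        n, c, w = self._shape
        w_out = w // self.pool
        gx = np.zeros((n, c, w_out, self.pool))
        ni, ci, wi = np.indices((n, c, w_out))
        gx[ni, ci, wi, self._argmax] = grad_out
        gx_full = np.zeros((n, c, w))
        gx_full[:, :, : w_out * self.pool] = gx.reshape(n, c, w_out * self.pool)
        return gx_full


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out):
        return grad_out.reshape(self._shape)


class Optimizer:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers
        self.caches = [
            [np.zeros_like(p) for p in layer.params] for layer in layers
        ]

    def step(self) -> None:
        raise NotImplementedError


class RMSProp(Optimizer):
    def __init__(self, layers, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-8):
        super().__init__(layers)
        self.lr, self.rho, self.eps = lr, rho, eps

    def step(self):
        for layer, caches in zip(self.layers, self.caches):
            for p, g, c in zip(layer.params, layer.grads, caches):
                c *= self.rho
                c += (1 - self.rho) * g * g
                p -= self.lr * g / (np.sqrt(c) + self.eps)


class Adagrad(Optimizer):
    def __init__(self, layers, lr: float = 1e-2, eps: float = 1e-8):
        super().__init__(layers)
        self.lr, self.eps = lr, eps

    def step(self):
        for layer, caches in zip(self.layers, self.caches):
            for p, g, c in zip(layer.params, layer.grads, caches):
                c += g * g
                p -= self.lr * g / (np.sqrt(c) + self.eps)


@dataclass
class Network:
    """A layer stack trained with minibatch SGD under MSE loss.

    Targets are {0, 1}; the single output neuron is linear, so the raw score
    is a regression toward class membership and is thresholded only by the
    downstream evaluation protocol.
    """

    layers: list[Layer]
    optimizer_name: str = "rmsprop"
    lr: float | None = None
    loss_history: list[float] = field(default_factory=list)

    def forward(self, x: np.ndarray, training: bool, rng) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def predict(self, x: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        rng = np.random.default_rng(0)  # unused: dropout is off at prediction
        outs = [
            self.forward(x[i : i + batch_size], training=False, rng=rng)
            for i in range(0, len(x), batch_size)
        ]
        if not outs:
            return np.empty(0)
        return np.concatenate(outs).reshape(-1)

    def _make_optimizer(self) -> Optimizer:
        if self.optimizer_name == "rmsprop":
            return RMSProp(self.layers, lr=self.lr or 1e-3)
        if self.optimizer_name == "adagrad":
            return Adagrad(self.layers, lr=self.lr or 1e-2)
        raise ValueError(f"unknown optimizer {self.optimizer_name!r}")

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 50,
        batch_size: int = 128,
        seed: int = 0,
    ) -> "Network":
        if len(x) == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(seed)
        opt = self._make_optimizer()
        y = np.asarray(y, dtype=float).reshape(-1)
        for _ in range(epochs):
            order = rng.permutation(len(x))
            epoch_loss = 0.0
            for lo in range(0, len(x), batch_size):
                idx = order[lo : lo + batch_size]
                xb, yb = x[idx], y[idx]
                pred = self.forward(xb, training=True, rng=rng).reshape(-1)
                diff = pred - yb
                epoch_loss += float(np.sum(diff * diff))
                g: np.ndarray = (2.0 / len(xb)) * diff.reshape(-1, 1)
                for layer in reversed(self.layers):
                    g = layer.backward(g)
                opt.step()
            self.loss_history.append(epoch_loss / len(x))
        return self

    def layer_of_type(self, cls):
        return [l for l in self.layers if isinstance(l, cls)]

    def activation_shapes(self, x: np.ndarray) -> list[tuple[int, ...]]:
        """Per-layer output shapes for one forward pass (model introspection)."""
        rng = np.random.default_rng(0)
        shapes = []
        for layer in self.layers:
            x = layer.forward(x, training=False, rng=rng)
            shapes.append(x.shape)
        return shapes
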