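"""Minimal fully-connected network core with manual backprop.

All networks in this package (the DNN affinity regressor, the PCM-GAN and
PCM-AAE encoder/decoder/generator/discriminator) are small multilayer
perceptrons on a few hundred units, so they are implemented directly on
NumPy: dense layers, batch normalization, dropout, ReLU/sigmoid/tanh
activations, and an Adam optimizer. Every source of randomness (weight
initialization, dropout masks) is drawn from a single
``numpy.random.Generator`` so training is reproducible for a fixed seed on
a single thread.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "BatchNorm",
    "Dropout",
    "Activation",
    "MLP",
    "Adam",
    "mse_loss",
    "bce_with_logits",
]


class Dense:
    """Affine layer ``y = x W + b`` with He-scaled initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW += self._x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class BatchNorm:
    """Batch normalization with running statistics for inference."""

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.dgamma = np.zeros(n)
        self.dbeta = np.zeros(n)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu) * inv_std
            self._cache = (xhat, inv_std)
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * inv_std
        return self.gamma * xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n = dout.shape[0]
        self.dgamma += (dout * xhat).sum(axis=0)
        self.dbeta += dout.sum(axis=0)
        dxhat = dout * self.gamma
        # standard batchnorm backward collapsed to two reductions
        return (inv_std / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class Dropout:
    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        if not train or self.p == 0.0:
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self):
        return []


class Activation:
    """Elementwise nonlinearity: 'relu', 'sigmoid' or 'tanh'."""

    def __init__(self, kind: str):
        if kind not in ("relu", "sigmoid", "tanh"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind
        self._out: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "relu":
            out = np.maximum(x, 0.0)
        elif self.kind == "sigmoid":
            out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500))),
                           np.exp(np.clip(x, -500, 500)) / (1.0 + np.exp(np.clip(x, -500, 500))))
        else:
            out = np.tanh(x)
        self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.kind == "relu":
            return dout * (self._out > 0)
        if self.kind == "sigmoid":
            return dout * self._out * (1.0 - self._out)
        return dout * (1.0 - self._out**2)

    def params(self):
        return []


class MLP:
    """A sequential stack of layers sharing one RNG for stochastic layers.

    ``widths`` gives the full layer-size chain, e.g. ``[601, 128, 64]``.
    ``batchnorm``/``dropout`` insert BatchNorm/Dropout after every hidden
    activation; the output layer is affine followed by ``out_activation``
    (or nothing when ``None``).
    """

    def __init__(
        self,
        widths: list[int],
        rng: np.random.Generator,
        hidden_activation: str = "relu",
        out_activation: str | None = None,
        batchnorm: bool = False,
        dropout: float = 0.0,
    ):
        if len(widths) < 2:
            raise ValueError("need at least input and output widths")
        if any(w <= 0 for w in widths):
            raise ValueError(f"layer widths must be positive, got {widths}")
        self.rng = rng
        self.layers: list = []
        for i in range(len(widths) - 2):
            self.layers.append(Dense(widths[i], widths[i + 1], rng))
            if batchnorm:
                self.layers.append(BatchNorm(widths[i + 1]))
            self.layers.append(Activation(hidden_activation))
            if dropout > 0:
                self.layers.append(Dropout(dropout))
        self.layers.append(Dense(widths[-2], widths[-1], rng))
        if out_activation is not None:
            self.layers.append(Activation(out_activation))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, self.rng)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0

    def state_arrays(self) -> list[np.ndarray]:
        """Flat list of all learnable/running arrays, for persistence."""
        arrays = []
        for layer in self.layers:
            for p, _ in layer.params():
                arrays.append(p)
            if isinstance(layer, BatchNorm):
                arrays.extend([layer.running_mean, layer.running_var])
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError("state array count mismatch")
        for dst, src in zip(own, arrays):
            if dst.shape != src.shape:
                raise ValueError("state array shape mismatch")
            dst[...] = src


class Adam:
    """Adam over the (param, grad) pairs of one or more networks."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.pairs = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self, lr_scale: float = 1.0) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            p -= (self.lr * lr_scale) * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient wrt ``pred``."""
    diff = pred - target
    n = diff.size
    return float((diff**2).sum() / n), 2.0 * diff / n


def bce_with_logits(logits: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy on raw logits.

    Returns the mean loss and its gradient wrt the logits,
    ``(sigmoid(logits) - target) / n``.
    """
    z = logits
    loss = np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z)))
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
    n = z.size
    return float(loss.sum() / n), (p - target) / n
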