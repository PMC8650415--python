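"""Baseline affinity regressors: feature scaling, DNN, RF and XGBoost.

The reference predictor is a fully connected network with three
ReLU-activated hidden layers of 200 units and a sigmoid output,
optimized with Adam on MSE. Because p-affinities live on roughly [0, 14]
while a sigmoid emits (0, 1), labels are divided by ``label_scale``
(default 14) during training and predictions are rescaled back, making
the prediction range exactly [0, label_scale]. Features should be
standardized to zero mean and unit variance (fit on the training rows
only) before training — this markedly speeds up convergence.

Random-forest (500 trees, at most 200 features per split) and XGBoost
regressors are provided as the classical baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.preprocessing import StandardScaler
from xgboost import XGBRegressor

from ._nn import MLP, Adam, mse_loss
from .dataset import PCMDataset


@dataclass
class Scaler:
    """Per-feature zero-mean/unit-variance scaling (population SD).

    Constant features keep a unit divisor so they pass through unchanged.
    Test data must be transformed with the training statistics only.
    """

    mean_: np.ndarray = None
    scale_: np.ndarray = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.scale_ + self.mean_


def fit_scaler(train_features: np.ndarray) -> Scaler:
    X = np.asarray(train_features, dtype=float)
    if X.size == 0:
        raise ValueError("cannot fit a scaler on an empty training set")
    ss = StandardScaler().fit(X)
    return Scaler(mean_=ss.mean_.copy(), scale_=ss.scale_.copy())


def apply_scaler(scaler: Scaler, features: np.ndarray) -> np.ndarray:
    return scaler.transform(features)


@dataclass
class DnnConfig:
    hidden_layers: list[int] = field(default_factory=lambda: [200, 200, 200])
    label_scale: float = 14.0
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0


class DnnRegressor:
    """Feed-forward affinity regressor (ReLU hidden, sigmoid output)."""

    def __init__(self, net: MLP, label_scale: float, loss_trace: np.ndarray):
        self.net = net
        self.label_scale = label_scale
        self.loss_trace = loss_trace  # per-epoch training MSE in label units

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.net.forward(X, train=False)[:, 0] * self.label_scale


def fit_dnn(X: np.ndarray, y: np.ndarray, config: DnnConfig | None = None) -> DnnRegressor:
    """Train the DNN regressor; deterministic for a fixed seed.

    Labels must lie in [0, label_scale] — they are squeezed through the
    sigmoid output by dividing by ``label_scale``.
    """
    config = config or DnnConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) == 0:
        raise ValueError("empty training set")
    if y.min() < 0 or y.max() > config.label_scale:
        raise ValueError(
            f"labels must lie in [0, {config.label_scale}], got "
            f"[{y.min():.3g}, {y.max():.3g}]"
        )
    rng = np.random.default_rng(config.seed)
    net = MLP([X.shape[1], *config.hidden_layers, 1], rng, out_activation="sigmoid")
    opt = Adam(net.params(), lr=config.learning_rate)
    target = (y / config.label_scale)[:, None]
    n = len(X)
    bs = min(config.batch_size, n)
    trace = np.zeros(config.epochs)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            net.zero_grad()
            out = net.forward(X[idx], train=True)
            loss, dout = mse_loss(out, target[idx])
            net.backward(dout)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        # report in p-affinity units
        trace[epoch] = (epoch_loss / n_batches) * config.label_scale**2
        if not np.isfinite(trace[epoch]):
            raise RuntimeError(f"DNN training diverged at epoch {epoch}")
    return DnnRegressor(net, config.label_scale, trace)


def fit_rf(X: np.ndarray, y: np.ndarray, n_estimators: int = 500,
           max_features: int = 200, seed: int = 0) -> RandomForestRegressor:
    """Random-forest baseline (500 trees, ≤200 features per split)."""
    X = np.asarray(X, dtype=float)
    if len(X) == 0:
        raise ValueError("empty training set")
    if max_features > X.shape[1]:
        warnings.warn(
            f"max_features={max_features} exceeds feature dim {X.shape[1]}; clipping",
            stacklevel=2,
        )
        max_features = X.shape[1]
    rf = RandomForestRegressor(n_estimators=n_estimators, max_features=max_features,
                               random_state=seed, n_jobs=1)
    rf.fit(X, np.asarray(y, dtype=float))
    return rf


def fit_xgboost(X: np.ndarray, y: np.ndarray, params: dict | None = None,
                seed: int = 0) -> XGBRegressor:
    """XGBoost baseline with the same contract as :func:`fit_rf`."""
    X = np.asarray(X, dtype=float)
    if len(X) == 0:
        raise ValueError("empty training set")
    params = dict(params or {})
    params.setdefault("n_estimators", 200)
    params.setdefault("n_jobs", 1)
    model = XGBRegressor(random_state=seed, **params)
    model.fit(X, np.asarray(y, dtype=float))
    return model


def fit_dnn_dataset(train: PCMDataset, config: DnnConfig | None = None,
                    scaler: Scaler | None = None) -> tuple[DnnRegressor, Scaler]:
    """Convenience: fit scaler (unless given) and DNN on a PCMDataset."""
    scaler = scaler or fit_scaler(train.X)
    return fit_dnn(scaler.transform(train.X), train.y, config), scaler
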