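"""EPA: the ensemble of generator-balanced predictors with an RF stacker.

Training regime: given a training set of *n* rows and *m* generator
handles, each member balances its own copy of the training set with
generated positives and fits a DNN regressor on it. The *m* fitted DNNs
then re-predict the *original* training rows, yielding an n × m
meta-prediction matrix, on which a single random-forest stacker is
fitted against the original (never synthetic) labels. Prediction runs
every member DNN and feeds the m-vector of member outputs to the
stacker.

ENB — the ensemble of non-balanced models — is the matched control: the
same regime with augmentation removed, members differing only through
their seeds. EPA/ENB comparisons should always be run on identical
train/test splits (a paired design).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .balance import augment_to_balance
from .dataset import PCMDataset
from .genmodels import GeneratorHandle
from .predict import DnnConfig, DnnRegressor, Scaler, fit_dnn, fit_rf, fit_scaler

DEFAULT_M = 24


@dataclass
class EpaModel:
    generators: list[GeneratorHandle] | None  # None for ENB
    dnns: list[DnnRegressor]
    stacker: RandomForestRegressor
    scaler: Scaler
    m: int

    def __post_init__(self):
        if len(self.dnns) != self.m or self.m < 2:
            raise ValueError("ensemble needs m ≥ 2 fitted members")


def _member_config(base: DnnConfig, seed: int) -> DnnConfig:
    cfg = DnnConfig(**{**base.__dict__})
    cfg.hidden_layers = list(base.hidden_layers)
    cfg.seed = seed
    return cfg


def _fit_stacker(meta: np.ndarray, y: np.ndarray, rf_config: dict | None, seed: int):
    rf_config = dict(rf_config or {})
    rf_config.setdefault("n_estimators", 500)
    rf_config.setdefault("max_features", meta.shape[1])
    return fit_rf(meta, y, seed=seed, **rf_config)


def train_epa(
    train: PCMDataset,
    generators: list[GeneratorHandle],
    dnn_config: DnnConfig | None = None,
    rf_config: dict | None = None,
    seed: int = 0,
) -> EpaModel:
    """Fit the EPA ensemble; see the module docstring for the regime."""
    m = len(generators)
    if m < 2:
        raise ValueError(f"EPA needs at least 2 generators, got {m}")
    if train.n_pos() == 0 or train.n_neg() == 0:
        raise ValueError("training set must contain both classes")
    dnn_config = dnn_config or DnnConfig()

    scaler = fit_scaler(train.X)  # shared so meta-features are comparable
    dnns: list[DnnRegressor] = []
    meta = np.zeros((len(train), m))
    X_orig = scaler.transform(train.X)
    for i, gen in enumerate(generators):
        balanced, _ = augment_to_balance(train, gen, seed=seed + i)
        try:
            dnn = fit_dnn(scaler.transform(balanced.X), balanced.y,
                          _member_config(dnn_config, seed + i))
        except Exception as exc:
            raise RuntimeError(f"ensemble member {i} failed to fit") from exc
        dnns.append(dnn)
        meta[:, i] = dnn.predict(X_orig)

    stacker = _fit_stacker(meta, train.y, rf_config, seed)
    return EpaModel(list(generators), dnns, stacker, scaler, m)


def train_enb(
    train: PCMDataset,
    m: int = DEFAULT_M,
    dnn_config: DnnConfig | None = None,
    rf_config: dict | None = None,
    seed: int = 0,
) -> EpaModel:
    """Fit the non-balanced control ensemble (no augmentation)."""
    if m < 2:
        raise ValueError(f"ENB needs at least 2 members, got {m}")
    if train.n_pos() == 0 or train.n_neg() == 0:
        raise ValueError("training set must contain both classes")
    dnn_config = dnn_config or DnnConfig()

    scaler = fit_scaler(train.X)
    X = scaler.transform(train.X)
    dnns: list[DnnRegressor] = []
    meta = np.zeros((len(train), m))
    for i in range(m):
        try:
            dnn = fit_dnn(X, train.y, _member_config(dnn_config, seed + i))
        except Exception as exc:
            raise RuntimeError(f"ensemble member {i} failed to fit") from exc
        dnns.append(dnn)
        meta[:, i] = dnn.predict(X)

    stacker = _fit_stacker(meta, train.y, rf_config, seed)
    return EpaModel(None, dnns, stacker, scaler, m)


def meta_matrix(model: EpaModel, features: np.ndarray) -> np.ndarray:
    """The n × m matrix of member predictions for given raw features."""
    features = np.asarray(features, dtype=float)
    if features.shape[1] != model.scaler.mean_.shape[0]:
        raise ValueError(
            f"feature dim {features.shape[1]} does not match training dim "
            f"{model.scaler.mean_.shape[0]}"
        )
    X = model.scaler.transform(features)
    return np.column_stack([dnn.predict(X) for dnn in model.dnns])


def predict_epa(model: EpaModel, features: np.ndarray) -> np.ndarray:
    """Predict affinities: member DNNs then the RF stacker."""
    return model.stacker.predict(meta_matrix(model, features))


def epa_vs_enb(
    dataset: PCMDataset,
    generators: list[GeneratorHandle],
    n_repeats: int = 20,
    dnn_config: DnnConfig | None = None,
    rf_config: dict | None = None,
    seed: int = 0,
) -> dict:
    """The paired EPA-versus-ENB comparison protocol.

    For each repetition a fresh random 80/20 pair split is drawn, EPA
    (with the supplied generators) and ENB (same member count, no
    augmentation) are trained on the identical training rows with the
    identical member seeds, and PCC, recall and AUC are measured on the
    identical test rows. Returns per-metric run vectors and the paired
    t-test comparison for each metric (positive mean difference favors
    EPA).
    """
    from .evalcv import (classification_metrics, paired_comparison,
                         regression_metrics, split_cv)

    runs = {k: ([], []) for k in ("pcc", "recall", "auc")}
    for rep in range(n_repeats):
        split = split_cv(dataset, "CV1", seed=seed + rep, parity_tol=None)
        train = dataset.subset(split.train_idx)
        test = dataset.subset(split.test_idx)
        epa_model = train_epa(train, generators, dnn_config, rf_config, seed=seed + 100 + rep)
        enb_model = train_enb(train, len(generators), dnn_config, rf_config,
                              seed=seed + 100 + rep)
        for model, col in ((enb_model, 0), (epa_model, 1)):
            pred = predict_epa(model, test.X)
            runs["pcc"][col].append(regression_metrics(test.y, pred).pcc)
            cls = classification_metrics(test.y, pred)
            runs["recall"][col].append(cls.recall)
            runs["auc"][col].append(cls.auc)
    out = {}
    for metric, (enb_runs, epa_runs) in runs.items():
        out[metric] = {
            "enb": np.array(enb_runs),
            "epa": np.array(epa_runs),
            "comparison": paired_comparison(enb_runs, epa_runs),
        }
    return out
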