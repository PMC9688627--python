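"""Classifier suite: LR, SVM-RBF, MLP, CNN, LSTM and CNNGRU.

The two machine-learning baselines are scikit-learn pipelines behind a
standard scaler. The four neural models run on the package's NumPy engine
(`eegdep._nn`) with the tuned shapes used throughout: the LSTM is four
stacked LSTM layers, batch normalization, and a sigmoid dense output with an
L2 kernel penalty; the CNNGRU is Conv1D -> max-pool -> GRU -> flatten ->
sigmoid dense. All train with binary cross-entropy, Adam, 100 epochs, batch
size 32, an 80/20 train/validation split, and a checkpoint that restores the
best-validation-loss weights.

Each six-feature sample is fed to the sequence models as (timesteps=6,
channels=1) in the canonical feature order; this axis convention is a
documented package choice, configurable through the feature order given to
the extraction step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from . import _nn
from .select import CVResult

__all__ = [
    "MODEL_KINDS",
    "ModelSpec",
    "TrainConfig",
    "NeuralNetClassifier",
    "build_model",
    "train_model",
    "compare_classifiers",
    "save_checkpoint",
    "load_checkpoint",
]

MODEL_KINDS = ("LR", "SVM_RBF", "MLP", "CNN", "LSTM", "CNNGRU")


@dataclass
class ModelSpec:
    """Declarative model description: kind + hyperparameter overrides + seed."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        kind = self.kind.upper().replace("-", "_").replace("+", "")
        if kind == "CNNGRU" or kind == "CNN_GRU":
            kind = "CNNGRU"
        if kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; one of {MODEL_KINDS}")
        self.kind = kind


@dataclass
class TrainConfig:
    """Training regime for the neural models (BCE loss, Adam optimizer)."""

    epochs: int = 100
    batch_size: int = 32
    validation_fraction: float = 0.2
    learning_rate: float = 1e-3
    checkpoint: bool = True

    def __post_init__(self):
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")


class NeuralNetClassifier(BaseEstimator, ClassifierMixin):
    """Binary sequence classifier over feature vectors, NumPy backend.

    Parameters
    ----------
    kind
        'MLP', 'CNN', 'LSTM' or 'CNNGRU'.
    lstm_units, conv_filters, kernel_size, pool_size, gru_units, mlp_units
        Architecture sizes (defaults are modest capacities for 6-dim inputs).
    l2
        L2 kernel-penalty coefficient on the LSTM output layer.
    standardize
        Fit a per-feature standard scaler on the training data (recommended:
        the features live on different scales, e.g. DFA vs entropies).
    random_state
        Seeds weight init, the train/validation split and batch shuffling;
        training is deterministic for a fixed seed.

    Fitted attributes: ``classes_``, ``net_``, ``history_``, ``mean_``,
    ``scale_``, ``n_features_in_``.
    """

    def __init__(
        self,
        kind="LSTM",
        lstm_units=(64, 64, 32, 32),
        conv_filters=32,
        kernel_size=3,
        pool_size=2,
        gru_units=32,
        mlp_units=(64, 32),
        l2=1e-3,
        epochs=100,
        batch_size=32,
        validation_fraction=0.2,
        learning_rate=1e-3,
        checkpoint=True,
        standardize=True,
        random_state=0,
    ):
        self.kind = kind
        self.lstm_units = lstm_units
        self.conv_filters = conv_filters
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.gru_units = gru_units
        self.mlp_units = mlp_units
        self.l2 = l2
        self.epochs = epochs
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.learning_rate = learning_rate
        self.checkpoint = checkpoint
        self.standardize = standardize
        self.random_state = random_state

    # -- architecture -------------------------------------------------------
    def _build(self, n_features: int) -> _nn.Sequential:
        rng = np.random.default_rng(self.random_state)
        kind = self.kind.upper()
        layers: list[_nn.Layer] = []
        if kind == "MLP":
            layers.append(_nn.Flatten())
            n_in = n_features
            for units in self.mlp_units:
                layers.append(_nn.Dense(n_in, units, activation="relu", rng=rng))
                n_in = units
            layers.append(_nn.Dense(n_in, 1, activation="sigmoid", rng=rng))
        elif kind == "CNN":
            t = n_features
            layers.append(
                _nn.Conv1D(1, self.conv_filters, self.kernel_size, "relu", rng=rng)
            )
            t -= self.kernel_size - 1
            layers.append(
                _nn.Conv1D(
                    self.conv_filters, self.conv_filters, self.kernel_size, "relu", rng=rng
                )
            )
            t -= self.kernel_size - 1
            layers.append(_nn.Flatten())
            layers.append(
                _nn.Dense(t * self.conv_filters, 1, activation="sigmoid", rng=rng)
            )
        elif kind == "LSTM":
            n_in = 1
            for i, units in enumerate(self.lstm_units):
                last = i == len(self.lstm_units) - 1
                layers.append(
                    _nn.LSTM(n_in, units, return_sequences=not last, rng=rng)
                )
                n_in = units
            layers.append(_nn.BatchNorm(n_in))
            layers.append(
                _nn.Dense(n_in, 1, activation="sigmoid", l2=self.l2, rng=rng)
            )
        elif kind == "CNNGRU":
            layers.append(
                _nn.Conv1D(1, self.conv_filters, self.kernel_size, "relu", rng=rng)
            )
            layers.append(_nn.MaxPool1D(self.pool_size))
            layers.append(
                _nn.GRU(self.conv_filters, self.gru_units, return_sequences=False, rng=rng)
            )
            layers.append(_nn.Flatten())
            layers.append(_nn.Dense(self.gru_units, 1, activation="sigmoid", rng=rng))
        else:
            raise ValueError(f"unknown neural model kind {self.kind!r}")
        return _nn.Sequential(layers)

    # -- sklearn API --------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, np.float64)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be (n_samples, n_features)")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(
                f"need exactly 2 classes, got {self.classes_.tolist()}"
            )
        self.n_features_in_ = X.shape[1]
        y01 = (y == self.classes_[1]).astype(np.float64)
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            self.scale_ = X.std(axis=0)
            self.scale_[self.scale_ == 0] = 1.0
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Xs = (X - self.mean_) / self.scale_
        Xseq = Xs[:, :, None]  # (n, timesteps, 1)
        self.net_ = self._build(X.shape[1])
        self.history_ = self.net_.fit(
            Xseq,
            y01,
            epochs=self.epochs,
            batch_size=self.batch_size,
            validation_fraction=self.validation_fraction,
            learning_rate=self.learning_rate,
            checkpoint=self.checkpoint,
            seed=self.random_state,
        )
        return self

    def _proba1(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = np.asarray(X, np.float64)
        Xs = (X - self.mean_) / self.scale_
        return self.net_.predict_proba(Xs[:, :, None])

    def predict_proba(self, X):
        p1 = self._proba1(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        p1 = self._proba1(X)
        return self.classes_[(p1 >= 0.5).astype(int)]


def build_model(spec: ModelSpec):
    """Instantiate an untrained estimator from a ModelSpec."""
    if spec.kind == "LR":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("lr", LogisticRegression(max_iter=1000, random_state=spec.seed)),
            ]
        )
    if spec.kind == "SVM_RBF":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svm", SVC(kernel="rbf", C=1.0, gamma="scale", random_state=spec.seed)),
            ]
        )
    return NeuralNetClassifier(
        kind=spec.kind, random_state=spec.seed, **spec.hyperparameters
    )


def train_model(model, X, y, config: TrainConfig | None = None):
    """Fit a model under a TrainConfig (neural models only honor the regime)."""
    config = config or TrainConfig()
    if isinstance(model, NeuralNetClassifier):
        model.set_params(
            epochs=config.epochs,
            batch_size=config.batch_size,
            validation_fraction=config.validation_fraction,
            learning_rate=config.learning_rate,
            checkpoint=config.checkpoint,
        )
    return model.fit(X, y)


def compare_classifiers(
    X,
    y,
    specs: list[ModelSpec],
    k: int = 10,
    seed: int = 0,
    train_config: TrainConfig | None = None,
) -> tuple[list[CVResult], pd.DataFrame]:
    """Fold-matched stratified k-fold accuracies plus a paired t-test matrix.

    Every spec sees the identical folds; the returned p-value matrix is
    symmetric with NaN on the diagonal (self-comparison undefined) and NaN
    wherever the paired score differences have zero variance.
    """
    if len(specs) < 2:
        raise ValueError("need at least two model specs to compare")
    X = np.asarray(X, np.float64)
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    results = []
    for spec in specs:
        scores = []
        for train_idx, test_idx in folds:
            model = build_model(spec)
            if isinstance(model, NeuralNetClassifier) and train_config is not None:
                train_model(model, X[train_idx], y[train_idx], train_config)
            else:
                model.fit(X[train_idx], y[train_idx])
            scores.append(float(np.mean(model.predict(X[test_idx]) == y[test_idx])))
        results.append(CVResult(kind="classifier", unit=spec.kind, scores=np.array(scores)))
    names = [r.unit for r in results]
    pmat = pd.DataFrame(np.full((len(specs), len(specs)), np.nan), index=names, columns=names)
    for i in range(len(results)):
        for j in range(i + 1, len(results)):
            diff = results[i].scores - results[j].scores
            if np.allclose(diff, 0.0) or np.std(diff) == 0:
                p = np.nan
            else:
                p = float(stats.ttest_rel(results[i].scores, results[j].scores).pvalue)
            pmat.iloc[i, j] = pmat.iloc[j, i] = p
    return results, pmat


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: NeuralNetClassifier, path: str | Path) -> Path:
    """Save weights (.npz) plus a JSON sidecar (params, classes, history)."""
    check_is_fitted(model, "net_")
    path = Path(path)
    arrays = {}
    for i, layer in enumerate(model.net_.layers):
        for name, value in layer.params.items():
            arrays[f"{i}:param:{name}"] = value
        for name, value in layer.state.items():
            arrays[f"{i}:state:{name}"] = value
    arrays["_scaler"] = np.vstack([model.mean_, model.scale_])
    arrays["_classes"] = model.classes_.astype(np.float64)
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in model.get_params().items()
        },
        "n_features_in": int(model.n_features_in_),
        "history": model.history_,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path.with_suffix(".npz")


def load_checkpoint(path: str | Path) -> NeuralNetClassifier:
    """Rebuild a fitted NeuralNetClassifier; predictions are bit-identical."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    params = {
        k: (tuple(v) if isinstance(v, list) else v)
        for k, v in sidecar["params"].items()
    }
    model = NeuralNetClassifier(**params)
    data = np.load(path.with_suffix(".npz"))
    scaler = data["_scaler"]
    model.mean_, model.scale_ = scaler[0], scaler[1]
    model.classes_ = data["_classes"]
    model.n_features_in_ = sidecar["n_features_in"]
    model.history_ = sidecar["history"]
    model.net_ = model._build(model.n_features_in_)
    for i, layer in enumerate(model.net_.layers):
        for name in layer.params:
            layer.params[name] = data[f"{i}:param:{name}"].copy()
        for name in layer.state:
            layer.state[name] = data[f"{i}:state:{name}"].copy()
    return model
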