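"""The heterogeneous base learners behind the ensemble, under one contract.

Six algorithms are supported — four shallow (k-nearest neighbors, RBF
support-vector classifier with probability calibration, random forest,
extra trees) and two neural (the in-package LSTM recurrent net, and a
multilayer perceptron). Every fitted model exposes the same contract:
probability of the positive (hepatotoxic) class per row, on a feature
matrix matching the training schema.

Defaults follow the tuned settings of the underlying study design:
KNN k=5; forest family n_estimators=500 (optional grid over
{100, 300, 500, 700} by validation AUC); LSTM 2 layers x 64 units,
dropout 0.2, Adam lr 0.001, 10 epochs, batch 128; MLP hidden (100, 50),
max 500 iterations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .errors import ConfigError, DegenerateLabels, SchemaError
from .featurization import FeatureMatrix
from .nn import LSTMClassifier

logger = logging.getLogger(__name__)

ALGORITHMS = ("knn", "svc", "rf", "et", "rnn", "mlp")

#: Candidate grid for the forest family when ``grid_search`` is enabled.
N_ESTIMATORS_GRID = (100, 300, 500, 700)

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "knn": {"k": 5},
    "svc": {"kernel": "rbf", "C": 1.0},
    "rf": {"n_estimators": 500, "grid_search": False},
    "et": {"n_estimators": 500, "grid_search": False},
    "rnn": {
        "units": 64,
        "layers": 2,
        "dropout": 0.2,
        "learning_rate": 0.001,
        "epochs": 10,
        "batch_size": 128,
        "input_shaping": "chunked",
        "seq_len": 32,
    },
    "mlp": {"hidden_sizes": (100, 50), "max_iter": 500},
}


@dataclass(frozen=True)
class ModelConfig:
    """Declarative spec of one base learner.

    ``hyperparameters`` overrides the algorithm's defaults; unknown keys are
    rejected so typos fail loudly.
    """

    algorithm: str
    hyperparameters: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ConfigError(f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}")
        unknown = set(self.hyperparameters) - set(DEFAULT_HYPERPARAMETERS[self.algorithm])
        if unknown:
            raise ConfigError(f"unknown hyperparameters for {self.algorithm}: {sorted(unknown)}")

    def resolved(self) -> dict:
        """Defaults merged with overrides."""
        out = dict(DEFAULT_HYPERPARAMETERS[self.algorithm])
        out.update(self.hyperparameters)
        return out

    def to_dict(self) -> dict:
        hp = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.resolved().items()}
        return {"algorithm": self.algorithm, "hyperparameters": hp, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        hp = {
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in d.get("hyperparameters", {}).items()
        }
        return cls(algorithm=d["algorithm"], hyperparameters=hp, seed=d.get("seed", 0))


@dataclass
class FittedModel:
    """A trained base learner bound to its training feature schema."""

    config: ModelConfig
    feature_names: list[str]
    estimator: object
    #: per-epoch mean training loss for neural members, empty otherwise
    training_log: list[float] = field(default_factory=list)


def _as_array(X) -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


def _validate_inputs(X: np.ndarray, y: np.ndarray) -> None:
    if X.shape[1] < 1:
        raise ConfigError("X must have at least one feature")
    if len(np.unique(y)) < 2:
        raise DegenerateLabels("training labels contain a single class")


def _make_estimator(config: ModelConfig):
    hp = config.resolved()
    alg, seed = config.algorithm, config.seed
    if alg == "knn":
        if hp["k"] < 1:
            raise ConfigError("knn.k must be >= 1")
        return KNeighborsClassifier(n_neighbors=hp["k"])
    if alg == "svc":
        if hp["C"] <= 0:
            raise ConfigError("svc.C must be > 0")
        # probability=True adds internal Platt calibration (soft voting
        # needs calibrated probability output)
        return SVC(kernel=hp["kernel"], C=hp["C"], probability=True, random_state=seed)
    if alg in ("rf", "et"):
        if hp["n_estimators"] < 1:
            raise ConfigError(f"{alg}.n_estimators must be >= 1")
        cls = RandomForestClassifier if alg == "rf" else ExtraTreesClassifier
        return cls(n_estimators=hp["n_estimators"], random_state=seed, n_jobs=1)
    if alg == "rnn":
        return LSTMClassifier(
            units=hp["units"],
            n_layers=hp["layers"],
            dropout=hp["dropout"],
            learning_rate=hp["learning_rate"],
            epochs=hp["epochs"],
            batch_size=hp["batch_size"],
            input_shaping=hp["input_shaping"],
            seq_len=hp["seq_len"],
            seed=seed,
        )
    if alg == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=tuple(hp["hidden_sizes"]),
            max_iter=hp["max_iter"],
            random_state=seed,
        )
    raise ConfigError(f"unknown algorithm {alg!r}")  # pragma: no cover


def _grid_search_forest(config: ModelConfig, X: np.ndarray, y: np.ndarray):
    """Pick n_estimators from the small grid by validation AUC."""
    tr, va = train_test_split(
        np.arange(len(y)), test_size=0.2, random_state=config.seed, stratify=y
    )
    best, best_auc = None, -np.inf
    for n in N_ESTIMATORS_GRID:
        cand_cfg = ModelConfig(
            config.algorithm,
            {**dict(config.hyperparameters), "n_estimators": n, "grid_search": False},
            config.seed,
        )
        est = _make_estimator(cand_cfg).fit(X[tr], y[tr])
        auc = roc_auc_score(y[va], est.predict_proba(X[va])[:, 1])
        if auc > best_auc:
            best, best_auc = n, auc
    logger.info("%s grid search selected n_estimators=%d (val AUC %.4f)", config.algorithm, best, best_auc)
    return _make_estimator(
        ModelConfig(
            config.algorithm,
            {**dict(config.hyperparameters), "n_estimators": best, "grid_search": False},
            config.seed,
        )
    ).fit(X, y)


def build_and_fit(config: ModelConfig, X_train, y) -> FittedModel:
    """Construct the configured learner and fit it on the training matrix.

    Deterministic given ``config.seed`` (neural members seed initialization,
    batching and dropout). MLP non-convergence within ``max_iter`` logs a
    warning but still returns the model.
    """
    Xa = _as_array(X_train)
    ya = np.asarray(y, dtype=int).ravel()
    _validate_inputs(Xa, ya)
    names = (
        list(X_train.feature_names)
        if isinstance(X_train, FeatureMatrix)
        else [f"f{i}" for i in range(Xa.shape[1])]
    )

    hp = config.resolved()
    if config.algorithm in ("rf", "et") and hp.get("grid_search"):
        est = _grid_search_forest(config, Xa, ya)
    else:
        est = _make_estimator(config)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            est.fit(Xa, ya)
        for w in caught:
            if issubclass(w.category, ConvergenceWarning):
                logger.warning("%s did not converge within max_iter", config.algorithm)

    training_log = list(getattr(est, "loss_history_", []) or getattr(est, "loss_curve_", []))
    return FittedModel(config=config, feature_names=names, estimator=est, training_log=training_log)


def predict_proba(model: FittedModel, X) -> np.ndarray:
    """Per-row probability of the positive class.

    Raises
    ------
    SchemaError
        If ``X`` carries feature names differing from the training schema.
    """
    if isinstance(X, FeatureMatrix) and list(X.feature_names) != list(model.feature_names):
        raise SchemaError("feature names do not match the model's training schema")
    Xa = _as_array(X)
    if Xa.shape[1] != len(model.feature_names):
        raise SchemaError(
            f"expected {len(model.feature_names)} features, got {Xa.shape[1]}"
        )
    proba = model.estimator.predict_proba(Xa)
    classes = list(getattr(model.estimator, "classes_", [0, 1]))
    return np.asarray(proba)[:, classes.index(1)]


def predict_label(probabilities, threshold: float = 0.5) -> np.ndarray:
    """Binarize probabilities: label 1 iff probability >= threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return (np.asarray(probabilities, dtype=float) >= threshold).astype(int)
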