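"""Classifier training: grid-searched tree ensembles, neural kinds, and the
stacked ensemble of frozen base models.

Tree models (random forest, extreme gradient boosting) are grid-searched
over the full hyperparameter lists with a held-out internal validation
split and refit on the whole training split. Neural kinds (ann, cnn1d,
lstm, gru, bilstm) run on the NumPy engine in :mod:`genopheno._nn`; the
recurrent and convolutional kinds consume the selected SNPs as a sequence
of one-channel steps in panel order. The stacked ensemble freezes base
models whose validation accuracy clears a threshold (default 0.92),
concatenates their two-unit output vectors and trains a small dense head
on top for a fixed number of epochs (default 10).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedShuffleSplit
from xgboost import XGBClassifier

from . import _nn
from .dataset_builder import FeatureDataset, SplitDataset

logger = logging.getLogger(__name__)

TREE_KINDS = ("rf", "xgb")
NEURAL_KINDS = ("ann", "cnn1d", "lstm", "gru", "bilstm")
MODEL_KINDS = TREE_KINDS + NEURAL_KINDS + ("ensemble",)


@dataclass(frozen=True)
class HyperParams:
    """One neural training configuration (the swept axes plus seed)."""

    activation: str = "sigmoid"
    dropout_rate: float = 0.2
    optimizer: str = "adam"
    batch_size: int = 10
    epochs: int = 10
    validation_split: float = 0.2
    seed: int = 0
    learning_rate: Optional[float] = None
    hidden_size: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.validation_split < 1.0:
            raise ValueError("validation_split must be in (0, 1)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class ModelGrid:
    """Named hyperparameter axes for one model kind."""

    model_kind: str
    axes: dict[str, list]

    def __post_init__(self) -> None:
        if not self.axes or any(not v for v in self.axes.values()):
            raise ValueError("grid axes must be non-empty")

    def combinations(self) -> list[dict[str, Any]]:
        names = list(self.axes)
        return [
            dict(zip(names, values))
            for values in itertools.product(*(self.axes[n] for n in names))
        ]

    def __len__(self) -> int:
        return int(np.prod([len(v) for v in self.axes.values()]))


#: the printed random-forest search lists
DEFAULT_RF_GRID = ModelGrid(
    "rf",
    {
        "criterion": ["gini", "entropy"],
        "min_samples_split": [0.01, 0.015, 0.02, 0.025],
        "max_depth": [None, 4, 5],
        "min_samples_leaf": [0.0025, 0.005, 0.01, 0.015],
        "max_features": ["sqrt", 0.3, 0.4, 0.5],
        "n_estimators": [500, 1000, 3000],
    },
)

#: the printed gradient-boosting search lists; "dar" in some write-ups is the
#: dart booster, and the three losses are the binary objectives below
DEFAULT_XGB_GRID = ModelGrid(
    "xgb",
    {
        "min_child_weight": [1, 5, 10],
        "gamma": [0.5, 1, 1.5, 2, 5],
        "subsample": [0.6, 0.8, 1.0],
        "colsample_bytree": [0.6, 0.8, 1.0],
        "max_depth": [3, 4, 5],
        "booster": ["gbtree", "gblinear", "dart"],
        "objective": ["binary:hinge", "binary:logistic", "binary:logitraw"],
    },
)

#: the neural sweep axes (shared by all five neural kinds)
DEFAULT_NEURAL_GRID_AXES: dict[str, list] = {
    "activation": ["sigmoid", "relu", "softmax"],
    "dropout_rate": [0.2, 0.3, 0.5],
    "optimizer": ["adam", "sgd", "rmsprop"],
    "batch_size": [1, 10, 15, 20],
    "validation_split": [0.2, 0.3, 0.4],
    "epochs": [10, 20, 50, 100],
}


def default_grid(kind: str) -> ModelGrid:
    if kind == "rf":
        return DEFAULT_RF_GRID
    if kind == "xgb":
        return DEFAULT_XGB_GRID
    if kind in NEURAL_KINDS:
        return ModelGrid(kind, {k: list(v) for k, v in DEFAULT_NEURAL_GRID_AXES.items()})
    raise ValueError(f"unknown model kind {kind!r}")


@dataclass
class TrainedModel:
    """A fitted classifier plus its configuration and validation accuracy."""

    kind: str
    hyperparams: dict[str, Any]
    estimator: Any
    validation_accuracy: float
    n_features: int
    history: Optional[dict[str, list[float]]] = None

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return predict_proba(self, features)


@dataclass(frozen=True)
class EnsembleConfig:
    """Stacked-ensemble construction knobs.

    Base models must exceed ``val_acc_threshold`` (default 0.92) to join the
    ensemble; the dense head trains for ``meta_epochs`` (default 10). When
    no candidate qualifies the default is an error; setting
    ``fallback_top_k`` instead admits the top-k candidates by validation
    accuracy, with a logged warning.
    """

    val_acc_threshold: float = 0.92
    meta_epochs: int = 10
    max_base_models: Optional[int] = None
    fallback_top_k: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_acc_threshold < 1.0:
            raise ValueError("val_acc_threshold must be in (0, 1)")


def _base_estimator(kind: str, seed: int):
    if kind == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if kind == "xgb":
        return XGBClassifier(
            random_state=seed,
            n_estimators=100,
            verbosity=0,
            n_jobs=1,
            eval_metric="logloss",
        )
    raise ValueError(f"unknown tree kind {kind!r}")


def train_tree_model(
    dataset: SplitDataset,
    kind: str,
    grid: Optional[ModelGrid] = None,
    seed: int = 0,
    validation_split: float = 0.2,
) -> TrainedModel:
    """Exhaustive grid search with a held-out validation split, refit on the
    full training split. The chosen configuration is logged and recorded."""
    if kind not in TREE_KINDS:
        raise ValueError(f"kind must be one of {TREE_KINDS}, got {kind!r}")
    grid = grid if grid is not None else default_grid(kind)
    if grid.model_kind != kind:
        raise ValueError(f"grid is for {grid.model_kind!r}, not {kind!r}")
    cv = StratifiedShuffleSplit(n_splits=1, test_size=validation_split, random_state=seed)
    search = GridSearchCV(
        _base_estimator(kind, seed),
        param_grid={k: list(v) for k, v in grid.axes.items()},
        scoring="accuracy",
        cv=cv,
        refit=True,
        n_jobs=1,
    )
    search.fit(dataset.train.features, dataset.train.labels)
    logger.info("%s grid search best params: %s", kind, search.best_params_)
    return TrainedModel(
        kind=kind,
        hyperparams=dict(search.best_params_),
        estimator=search.best_estimator_,
        validation_accuracy=float(search.best_score_),
        n_features=dataset.train.n_features,
    )


def _build_network(kind: str, n_features: int, hp: HyperParams) -> _nn.Sequential:
    rng = np.random.default_rng(hp.seed)
    act = hp.activation
    hidden = hp.hidden_size or max(8, min(64, 2 * n_features))
    if kind == "ann":
        h2 = max(4, hidden // 2)
        layers = [
            _nn.Dense(n_features, hidden, rng),
            _nn.Activation(act),
            _nn.Dropout(hp.dropout_rate, rng),
            _nn.Dense(hidden, h2, rng),
            _nn.Activation(act),
            _nn.Dense(h2, 2, rng),
        ]
        return _nn.Sequential(layers)
    if kind == "cnn1d":
        kernel = min(3, n_features)
        n_filters = 8
        layers = [
            _nn.Conv1D(1, n_filters, kernel, rng),
            _nn.Activation("relu"),
            _nn.Dropout(hp.dropout_rate, rng),
            _nn.GlobalAvgPool1D(),
            _nn.Dense(n_filters, 16, rng),
            _nn.Activation(act),
            _nn.Dense(16, 2, rng),
        ]
        return _nn.Sequential(layers, sequence_input=True)
    recurrent_hidden = hp.hidden_size or 16
    if kind == "lstm":
        core: _nn.Layer = _nn.LSTM(1, recurrent_hidden, rng)
        width = recurrent_hidden
    elif kind == "gru":
        core = _nn.GRU(1, recurrent_hidden, rng)
        width = recurrent_hidden
    elif kind == "bilstm":
        core = _nn.BiLSTM(1, recurrent_hidden, rng)
        width = 2 * recurrent_hidden
    else:
        raise ValueError(f"unknown neural kind {kind!r}")
    layers = [core, _nn.Dropout(hp.dropout_rate, rng), _nn.Dense(width, 2, rng)]
    return _nn.Sequential(layers, sequence_input=True)


def train_neural_model(
    dataset: SplitDataset, kind: str, hp: Optional[HyperParams] = None
) -> TrainedModel:
    """Assemble and train one neural kind on the training split.

    The recurrent and 1-D convolutional kinds read the feature vector as a
    length-n_snps sequence of one-channel steps in panel order. The final
    epoch's held-out accuracy is the model's validation accuracy.
    """
    if kind not in NEURAL_KINDS:
        raise ValueError(f"kind must be one of {NEURAL_KINDS}, got {kind!r}")
    hp = hp or HyperParams()
    net = _build_network(kind, dataset.train.n_features, hp)
    history = net.fit(
        dataset.train.features,
        dataset.train.labels,
        epochs=hp.epochs,
        batch_size=hp.batch_size,
        validation_split=hp.validation_split,
        optimizer=hp.optimizer,
        learning_rate=hp.learning_rate,
        seed=hp.seed,
    )
    return TrainedModel(
        kind=kind,
        hyperparams=asdict(hp),
        estimator=net,
        validation_accuracy=float(history["val_accuracy"][-1]),
        n_features=dataset.train.n_features,
        history=history,
    )


def _combo_key(combo: dict[str, Any]) -> str:
    return json.dumps(combo, sort_keys=True, default=str)


def hyperparameter_sweep(
    dataset: SplitDataset,
    kind: str,
    grid: Optional[ModelGrid] = None,
    seed: int = 0,
    journal_path: Optional[str | Path] = None,
) -> list[TrainedModel]:
    """Enumerate the full Cartesian product of the grid and rank the results.

    Models are sorted by validation accuracy descending, ties keeping
    enumeration order. With ``journal_path`` the sweep is resumable:
    finished combinations are recorded as JSON lines and reloaded (without
    their fitted estimators) instead of being retrained.
    """
    grid = grid if grid is not None else default_grid(kind)
    done: dict[str, float] = {}
    journal = Path(journal_path) if journal_path else None
    if journal and journal.exists():
        for line in journal.read_text().splitlines():
            entry = json.loads(line)
            done[entry["key"]] = entry["validation_accuracy"]
    results: list[TrainedModel] = []
    for combo in grid.combinations():
        key = _combo_key(combo)
        if key in done:
            results.append(
                TrainedModel(kind, dict(combo), None, done[key], dataset.train.n_features)
            )
            continue
        if kind in TREE_KINDS:
            model = train_tree_model(
                dataset, kind, ModelGrid(kind, {k: [v] for k, v in combo.items()}), seed=seed
            )
        else:
            model = train_neural_model(dataset, kind, HyperParams(seed=seed, **combo))
        results.append(model)
        if journal:
            with journal.open("a") as fh:
                fh.write(
                    json.dumps({"key": key, "validation_accuracy": model.validation_accuracy})
                    + "\n"
                )
    order = sorted(
        range(len(results)), key=lambda i: -results[i].validation_accuracy
    )
    return [results[i] for i in order]


class StackedEnsemble:
    """Frozen base models feeding a trainable dense head.

    The bases' class-score vectors are concatenated into the head's input;
    base parameters are never updated while the head trains.
    """

    def __init__(self, bases: list[TrainedModel], head: _nn.Sequential) -> None:
        self.bases = bases
        self.head = head

    def _stack(self, X: np.ndarray) -> np.ndarray:
        return np.hstack([predict_proba(m, X) for m in self.bases])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.head.predict_proba(self._stack(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def build_stacked_ensemble(
    candidates: Sequence[TrainedModel],
    dataset: SplitDataset,
    config: Optional[EnsembleConfig] = None,
) -> TrainedModel:
    """Stack the qualifying candidates and train the meta head.

    Candidates qualify when validation accuracy strictly exceeds
    ``config.val_acc_threshold``; qualifying models are frozen and their
    concatenated outputs feed a dense head trained for ``config.meta_epochs``
    epochs on the training split.
    """
    config = config or EnsembleConfig()
    usable = [m for m in candidates if m.estimator is not None]
    qualifying = [m for m in usable if m.validation_accuracy > config.val_acc_threshold]
    if not qualifying:
        if config.fallback_top_k:
            qualifying = sorted(
                usable, key=lambda m: -m.validation_accuracy
            )[: config.fallback_top_k]
            logger.warning(
                "no candidate exceeded val_acc_threshold=%.3f; falling back to top %d",
                config.val_acc_threshold,
                len(qualifying),
            )
        if not qualifying:
            raise ValueError(
                "no candidate model exceeds the validation-accuracy threshold "
                f"{config.val_acc_threshold}"
            )
    if config.max_base_models is not None:
        qualifying = sorted(qualifying, key=lambda m: -m.validation_accuracy)[
            : config.max_base_models
        ]
    rng = np.random.default_rng(config.seed)
    width = 2 * len(qualifying)
    head = _nn.Sequential(
        [
            _nn.Dense(width, max(8, width), rng),
            _nn.Activation("relu"),
            _nn.Dense(max(8, width), 2, rng),
        ]
    )
    ensemble = StackedEnsemble(list(qualifying), head)
    Z = ensemble._stack(dataset.train.features)
    history = head.fit(
        Z,
        dataset.train.labels,
        epochs=config.meta_epochs,
        batch_size=10,
        validation_split=0.2,
        optimizer="adam",
        seed=config.seed,
    )
    return TrainedModel(
        kind="ensemble",
        hyperparams={
            "val_acc_threshold": config.val_acc_threshold,
            "meta_epochs": config.meta_epochs,
            "n_base_models": len(qualifying),
            "base_kinds": [m.kind for m in qualifying],
        },
        estimator=ensemble,
        validation_accuracy=float(history["val_accuracy"][-1]),
        n_features=dataset.train.n_features,
        history=history,
    )


def predict_proba(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Per-sample two-class score vectors (non-negative, rows sum to 1).

    Raw scores that are not already probabilities (e.g. hinge or raw-margin
    boosting objectives) are squashed through a sigmoid before renormalising.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[1] if X.ndim == 2 else X.shape} does not "
            f"match model width {model.n_features}"
        )
    est = model.estimator
    if est is None:
        raise ValueError("model was reloaded from a sweep journal without its estimator")
    p = np.asarray(est.predict_proba(X), dtype=float)
    if p.ndim == 1:
        p = np.column_stack([1.0 - p, p])
    if (p < 0).any() or (p > 1).any() or not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        p = 1.0 / (1.0 + np.exp(-np.clip(p, -500, 500)))
        p = p / p.sum(axis=1, keepdims=True)
    return p
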