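"""The five-classifier suite behind a single train/predict contract.

Flat-input models (linear SVM, RBF-kernel SVM, random forest, DNN) consume
the 480-dimensional flattened snapshot; the CNN consumes the (24, 20)
matrix directly. Every trained model returns one finite real-valued score
per example — a margin, a positive-vote fraction, or a network output —
with higher meaning more DRE-like; thresholding happens only in evaluation.

Architectures:

* DNN: 480 -> 600 -> 500 -> 400 -> 1, PReLU after each hidden layer,
  dropout 0.3 between hidden layers, MSE loss, RMSProp, 50 epochs.
* CNN: conv(64 kernels, 24x2, stride 1) -> PReLU -> conv(64, 1x2) -> PReLU
  -> max-pool(1x2) -> dropout 0.5 -> dense 300 -> PReLU -> dropout 0.5
  -> dense 300 -> PReLU -> dropout 0.3 -> dense 1; MSE loss, Adagrad.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC, LinearSVC

from ..intervals import GenomicInterval
from ..preprocessing import LabeledExample
from .nn import (
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    FullHeightConv,
    MaxPool1D,
    Network,
    PReLU,
)

__all__ = [
    "ModelKind",
    "ModelConfig",
    "TrainedModel",
    "PredictionScoreSet",
    "build_model",
    "build_dnn",
    "build_cnn",
    "build_linear_svm",
    "build_kernel_svm",
    "build_random_forest",
    "train",
    "predict_scores",
    "examples_to_arrays",
]

ModelKind = Literal["linear_svm", "kernel_svm", "random_forest", "dnn", "cnn"]

N_MARKS_DEFAULT = 24
N_BINS_DEFAULT = 20


@dataclass
class ModelConfig:
    """Hyperparameters for one classifier of the suite.

    Defaults follow the published architecture for the neural models; the
    SVM/forest defaults (C=1, gamma=1/d, 100 trees, unlimited depth) are the
    exposed tuning knobs.
    """

    kind: ModelKind = "cnn"
    epochs: int = 50
    batch_size: int = 128
    seed: int = 0
    n_marks: int = N_MARKS_DEFAULT
    n_bins: int = N_BINS_DEFAULT
    hyperparams: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.n_marks * self.n_bins


@dataclass
class TrainedModel:
    """A fitted classifier plus its input-shape contract."""

    config: ModelConfig
    estimator: object
    input_shape: tuple[int, ...]  # per-example shape: (480,) or (24, 20)

    def scores(self, x: np.ndarray) -> np.ndarray:
        if x.ndim == 0 or x.shape[1:] != self.input_shape:
            raise ValueError(
                f"expected input of shape (n, *{self.input_shape}), got {x.shape}"
            )
        if len(x) == 0:
            return np.empty(0)
        est = self.estimator
        if isinstance(est, Network):
            return est.predict(x)
        if isinstance(est, RandomForestClassifier):
            return est.predict_proba(x)[:, list(est.classes_).index(1)]
        return est.decision_function(x)


@dataclass
class PredictionScoreSet:
    """Raw real-valued scores aligned with their genomic locations."""

    locations: list[GenomicInterval]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.locations) != len(self.scores):
            raise ValueError("locations and scores length mismatch")
        if len(self.scores) and not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def __len__(self) -> int:
        return len(self.scores)


def build_dnn(config: ModelConfig) -> Network:
    """Three PReLU hidden layers (600/500/400) with dropout 0.3; RMSProp."""
    rng = np.random.default_rng(config.seed)
    d = config.n_features
    layers = [
        Dense(d, 600, rng), PReLU(), Dropout(0.3),
        Dense(600, 500, rng), PReLU(), Dropout(0.3),
        Dense(500, 400, rng), PReLU(), Dropout(0.3),
        Dense(400, 1, rng),
    ]
    hp = config.hyperparams
    return Network(layers, optimizer_name=hp.get("optimizer", "rmsprop"),
                   lr=hp.get("lr"))


def build_cnn(config: ModelConfig) -> Network:
    """Two conv layers (64 full-height 24x2 kernels, then 64 1x2), pool, dense."""
    rng = np.random.default_rng(config.seed)
    w1 = config.n_bins - 1          # 19 at defaults
    w2 = w1 - 1                     # 18
    w_pool = w2 // 2                # 9
    layers = [
        FullHeightConv(config.n_marks, 2, 64, rng), PReLU(),
        Conv1D(64, 64, 2, rng), PReLU(),
        MaxPool1D(2),
        Flatten(), Dropout(0.5),
        Dense(64 * w_pool, 300, rng), PReLU(), Dropout(0.5),
        Dense(300, 300, rng), PReLU(), Dropout(0.3),
        Dense(300, 1, rng),
    ]
    hp = config.hyperparams
    return Network(layers, optimizer_name=hp.get("optimizer", "adagrad"),
                   lr=hp.get("lr"))


def build_linear_svm(config: ModelConfig) -> LinearSVC:
    hp = config.hyperparams
    return LinearSVC(C=hp.get("C", 1.0), max_iter=hp.get("max_iter", 10000),
                     random_state=config.seed)


def build_kernel_svm(config: ModelConfig) -> SVC:
    hp = config.hyperparams
    # gamma="auto" is 1/d, the documented default RBF width
    return SVC(kernel="rbf", C=hp.get("C", 1.0), gamma=hp.get("gamma", "auto"),
               random_state=config.seed)


def build_random_forest(config: ModelConfig) -> RandomForestClassifier:
    hp = config.hyperparams
    return RandomForestClassifier(
        n_estimators=hp.get("n_trees", 100),
        max_depth=hp.get("max_depth"),
        random_state=config.seed,
        n_jobs=1,
    )


_BUILDERS = {
    "dnn": build_dnn,
    "cnn": build_cnn,
    "linear_svm": build_linear_svm,
    "kernel_svm": build_kernel_svm,
    "random_forest": build_random_forest,
}


def build_model(config: ModelConfig):
    try:
        return _BUILDERS[config.kind](config)
    except KeyError:
        raise ValueError(f"unknown model kind {config.kind!r}") from None


def examples_to_arrays(
    examples: Sequence[LabeledExample], kind: ModelKind
) -> tuple[np.ndarray, np.ndarray]:
    """Stack examples into the model's input array plus the {0,1} label vector."""
    if not examples:
        raise ValueError("empty example list")
    snaps = np.stack([e.snapshot.values for e in examples])
    y = np.array([e.label for e in examples], dtype=float)
    if kind == "cnn":
        return snaps, y
    return snaps.reshape(len(examples), -1), y


def train(
    model,
    train_set: Sequence[LabeledExample] | tuple[np.ndarray, np.ndarray],
    config: ModelConfig,
) -> TrainedModel:
    """Fit any suite model on labeled examples; deterministic under config.seed."""
    if isinstance(train_set, tuple):
        x, y = train_set
    else:
        x, y = examples_to_arrays(train_set, config.kind)
    if len(x) == 0:
        raise ValueError("empty training set")
    if isinstance(model, Network):
        model.fit(x, y, epochs=config.epochs, batch_size=config.batch_size,
                  seed=config.seed)
    else:
        if len(np.unique(y)) < 2:
            raise ValueError("margin/ensemble models need both classes present")
        model.fit(x, y.astype(int))
    input_shape = x.shape[1:]
    return TrainedModel(config=config, estimator=model, input_shape=input_shape)


def predict_scores(
    model: TrainedModel,
    examples: Sequence[LabeledExample] | np.ndarray,
    locations: Sequence[GenomicInterval] | None = None,
) -> PredictionScoreSet:
    """Score examples; no thresholding is applied here."""
    if isinstance(examples, np.ndarray):
        x = examples
        locs = list(locations or [])
        if locations is None:
            raise ValueError("locations required when passing raw arrays")
    else:
        if not examples:
            return PredictionScoreSet(locations=[], scores=np.empty(0))
        x, _ = examples_to_arrays(examples, model.config.kind)
        locs = [e.location for e in examples]
    return PredictionScoreSet(locations=locs, scores=model.scores(x))
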