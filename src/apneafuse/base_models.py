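"""The three base classifiers operating on 240×3 feature matrices.

All three are small 1-D CNN-family networks previously proposed for
ECG-based apnea detection:

* ``wang_cnn`` — two conv blocks (kernel 3, 64 filters, ReLU, batch
  norm, max-pool 2), then dense 100 → dense 10 → softmax over 2 classes.
* ``sharan_cnn`` — three conv blocks (kernel 10; 64/128/256 filters,
  ReLU, max-pool 2), then dense 64 → dense 256 → softmax.
* ``almutairi_cnn_lstm`` — each minute is split into 4 consecutive
  60×3 sub-windows; a shared CNN stack (kernel 3; 64/128/16 filters with
  batch norm, max-pool 2 and dropout 0.2) encodes every sub-window, an
  LSTM with 64 units runs across the 4 steps, then dense 64 → softmax.

Training uses softmax cross-entropy (equivalent to binary cross-entropy
for two one-hot classes) with Adam, defaulting to 100 epochs at batch
size 64 and step size 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nnkit
from .io import CLASSES
from .preprocessing import GRID_SIZE

ARCH_NAMES = ("wang_cnn", "sharan_cnn", "almutairi_cnn_lstm")

__all__ = [
    "ARCH_NAMES",
    "ArchitectureSpec",
    "TrainingContract",
    "ScoreMatrix",
    "build_model",
    "train",
    "predict_proba",
    "stack_scores",
    "features_to_array",
]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Which base architecture to build and the number of classes."""

    name: str
    k: int = 2

    def __post_init__(self):
        if self.name not in ARCH_NAMES:
            raise ValueError(f"unknown architecture {self.name!r}; choose from {ARCH_NAMES}")


@dataclass(frozen=True)
class TrainingContract:
    """Optimisation settings: Adam on cross-entropy."""

    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0


@dataclass
class ScoreMatrix:
    """Per-sample l×k class-probability block from the l base models."""

    probs: np.ndarray  # (n, l, k)
    labels: np.ndarray  # (n,) integer class indices
    model_names: list = field(default_factory=list)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.probs.ndim != 3:
            raise ValueError(f"probs must be (n, l, k), got shape {self.probs.shape}")
        if len(self.labels) != self.probs.shape[0]:
            raise ValueError("labels and probs disagree on sample count")
        sums = self.probs.sum(axis=2)
        if self.probs.size and (
            np.any(self.probs < -1e-9) or np.any(np.abs(sums - 1.0) > 1e-6)
        ):
            raise ValueError("each classifier row must be a probability simplex")

    @property
    def n_classifiers(self) -> int:
        return self.probs.shape[1]

    @property
    def n_classes(self) -> int:
        return self.probs.shape[2]


def _conv_block(in_ch, filters, kernel, rng, *, batchnorm=False, dropout=0.0):
    layers = [nnkit.Conv1D(in_ch, filters, kernel, rng), nnkit.ReLU()]
    if batchnorm:
        layers.append(nnkit.BatchNorm(filters))
    layers.append(nnkit.MaxPool1D(2))
    if dropout > 0:
        layers.append(nnkit.Dropout(dropout, rng))
    return layers


def build_model(
    spec: ArchitectureSpec, input_shape: tuple[int, int] = (GRID_SIZE, 3), seed: int = 0
) -> nnkit.Sequential:
    """Instantiate one of the three architectures for the given input shape.

    ``input_shape`` is ``(240, 3)`` for the two plain CNNs; the CNN-LSTM
    accepts either ``(240, 3)`` (sub-windowed internally) or ``(4, 60, 3)``.
    """
    rng = np.random.default_rng(seed)
    k = spec.k
    if spec.name in ("wang_cnn", "sharan_cnn"):
        if tuple(input_shape) != (GRID_SIZE, 3):
            raise ValueError(f"{spec.name} expects input shape {(GRID_SIZE, 3)}, got {input_shape}")
        L, C = input_shape
        if spec.name == "wang_cnn":
            layers = []
            layers += _conv_block(C, 64, 3, rng, batchnorm=True)
            layers += _conv_block(64, 64, 3, rng, batchnorm=True)
            flat = (L // 2 // 2) * 64
            layers += [
                nnkit.Flatten(),
                nnkit.Dense(flat, 100, rng),
                nnkit.ReLU(),
                nnkit.Dense(100, 10, rng),
                nnkit.ReLU(),
                nnkit.Dense(10, k, rng),
            ]
        else:
            layers = []
            layers += _conv_block(C, 64, 10, rng)
            layers += _conv_block(64, 128, 10, rng)
            layers += _conv_block(128, 256, 10, rng)
            flat = (L // 2 // 2 // 2) * 256
            layers += [
                nnkit.Flatten(),
                nnkit.Dense(flat, 64, rng),
                nnkit.ReLU(),
                nnkit.Dense(64, 256, rng),
                nnkit.ReLU(),
                nnkit.Dense(256, k, rng),
            ]
        return nnkit.Sequential(layers, seed=seed)

    # almutairi_cnn_lstm
    shape = tuple(input_shape)
    if shape == (GRID_SIZE, 3):
        t_steps, sub_len, C = 4, GRID_SIZE // 4, 3
        head = [nnkit.Reshape((t_steps, sub_len, C))]
    elif len(shape) == 3 and shape[0] * shape[1] == GRID_SIZE and shape[2] == 3:
        t_steps, sub_len, C = shape
        head = []
    else:
        raise ValueError(
            f"almutairi_cnn_lstm expects (240, 3) or (4, 60, 3), got {input_shape}"
        )
    cnn = []
    cnn += _conv_block(C, 64, 3, rng, batchnorm=True, dropout=0.2)
    cnn += _conv_block(64, 128, 3, rng, batchnorm=True, dropout=0.2)
    cnn += _conv_block(128, 16, 3, rng, batchnorm=True, dropout=0.2)
    cnn.append(nnkit.Flatten())
    flat = (sub_len // 2 // 2 // 2) * 16
    layers = head + [
        nnkit.TimeDistributed(cnn),
        nnkit.LSTM(flat, 64, rng),
        nnkit.Dense(64, 64, rng),
        nnkit.ReLU(),
        nnkit.Dense(64, k, rng),
    ]
    return nnkit.Sequential(layers, seed=seed)


def features_to_array(matrices) -> tuple[np.ndarray, np.ndarray]:
    """Stack clear FeatureMatrix objects into (X (n,240,3), y (n,)) arrays."""
    from .io import as_class_index

    clear = [fm for fm in matrices if fm.quality == "clear"]
    if not clear:
        return np.zeros((0, GRID_SIZE, 3)), np.zeros(0, dtype=int)
    X = np.stack([fm.values for fm in clear])
    y = np.array([as_class_index(fm.label) for fm in clear], dtype=int)
    return X, y


def train(
    model: nnkit.Sequential,
    X: np.ndarray,
    y: np.ndarray,
    contract: TrainingContract = TrainingContract(),
) -> list[dict]:
    """Train in place; returns per-epoch ``{"loss", "accuracy"}`` history."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2 and contract.epochs > 0:
        raise ValueError(
            f"training set holds a single class ({CLASSES[y[0]] if len(y) else 'empty'}); "
            "need at least one sample per class"
        )
    rng = np.random.default_rng(contract.seed)
    return model.fit(
        X,
        y,
        epochs=contract.epochs,
        batch_size=contract.batch_size,
        lr=contract.learning_rate,
        rng=rng,
    )


def predict_proba(model: nnkit.Sequential, X: np.ndarray) -> np.ndarray:
    """Class probabilities (n, k); rows on the simplex."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 3 or X.shape[1:] != (GRID_SIZE, 3):
        raise ValueError(f"expected input (n, {GRID_SIZE}, 3), got {X.shape}")
    return model.predict_proba(X)


def stack_scores(per_model_probs, labels, model_names=None) -> ScoreMatrix:
    """Assemble per-classifier (n, k) blocks into one (n, l, k) ScoreMatrix."""
    probs = np.stack(per_model_probs, axis=1)
    return ScoreMatrix(
        probs=probs,
        labels=np.asarray(labels, dtype=int),
        model_names=list(model_names or [f"model_{j}" for j in range(probs.shape[1])]),
    )
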