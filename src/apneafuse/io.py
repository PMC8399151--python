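"""Record and artifact I/O.

ECG records come in two layouts: the PhysioNet-style WFDB signal +
minute-wise apnea annotation pair (requires the optional ``wfdb``
package) and a plain-text CSV dialect used by the synthetic generator:
two columns ``sample_index,amplitude_mV`` with a header, plus a sidecar
``<record_id>.labels`` file holding one character per minute (``A`` for
apnea, ``N`` for normal).

Feature sets and score matrices are persisted as ``.npz`` archives; the
run configuration is a flat YAML file.  Every persisted artifact
round-trips losslessly.

Conventions used throughout the package: sample indices are 0-based,
minute ``m`` covers the half-open sample window ``[m*60*fs, (m+1)*60*fs)``,
and a trailing partial minute is dropped rather than padded.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: Class order used everywhere: index 0 = apnea (the positive class).
CLASSES = ("apnea", "normal")

_LABEL_ALIASES = {
    "A": 0, "a": 0, "apnea": 0, "0": 0,
    "N": 1, "n": 1, "normal": 1, "1": 1,
}


def as_class_index(label) -> int:
    """Map a label (``'A'``/``'N'``, full name, or 0/1) to its class index."""
    if isinstance(label, (int, np.integer)):
        if label in (0, 1):
            return int(label)
        raise ValueError(f"unknown class index {label!r}; expected 0 (apnea) or 1 (normal)")
    try:
        return _LABEL_ALIASES[str(label)]
    except KeyError:
        raise ValueError(f"unknown label {label!r}; expected one of A/N/apnea/normal") from None


def labels_to_indices(labels) -> np.ndarray:
    return np.array([as_class_index(l) for l in labels], dtype=int)


@dataclass
class EcgRecord:
    """A single-lead ECG record with per-minute apnea/normal labels."""

    record_id: str
    samples: np.ndarray
    fs: float = 100.0
    minute_labels: np.ndarray = field(default_factory=lambda: np.array([], dtype="<U1"))

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        labels = ["AN"[as_class_index(l)] for l in self.minute_labels]
        self.minute_labels = np.array(labels, dtype="<U1")

    @property
    def n_full_minutes(self) -> int:
        """Number of labelled minutes fully covered by the signal."""
        spm = int(round(60 * self.fs))
        return min(len(self.minute_labels), len(self.samples) // spm)

    def minute_window(self, m: int) -> tuple[int, int]:
        """Half-open sample range ``[start, stop)`` of minute ``m``."""
        spm = int(round(60 * self.fs))
        return m * spm, (m + 1) * spm


def read_record(path, format: str = "csv", fs: float = 100.0) -> EcgRecord:
    """Read an ECG record plus its minute annotations.

    Parameters
    ----------
    path
        For ``csv``: the signal CSV (sidecar ``<stem>.labels`` must sit
        next to it).  For ``wfdb``: the record path without extension.
    format
        ``"csv"`` or ``"wfdb"``.
    fs
        Sampling rate assumed for CSV input (WFDB carries its own).
    """
    path = Path(path)
    if format == "csv":
        if not path.exists():
            raise FileNotFoundError(f"record file not found: {path}")
        frame = pd.read_csv(path)
        required = {"sample_index", "amplitude_mV"}
        if not required.issubset(frame.columns):
            raise ValueError(
                f"CSV record {path} must have header columns {sorted(required)}"
            )
        label_path = path.with_suffix(".labels")
        if not label_path.exists():
            raise FileNotFoundError(
                f"missing minute-label sidecar for record {path.stem!r}: {label_path}"
            )
        labels = list(label_path.read_text().strip())
        return EcgRecord(
            record_id=path.stem,
            samples=frame["amplitude_mV"].to_numpy(dtype=float),
            fs=fs,
            minute_labels=np.array(labels),
        )
    if format == "wfdb":
        try:
            import wfdb
        except ImportError as exc:  # pragma: no cover - wfdb optional
            raise ImportError(
                "reading WFDB records requires the optional 'wfdb' package "
                "(pip install wfdb); the CSV dialect needs no extras"
            ) from exc
        rec = wfdb.rdrecord(str(path))
        try:
            ann = wfdb.rdann(str(path), "apn")
        except FileNotFoundError as exc:  # pragma: no cover
            raise FileNotFoundError(
                f"missing apnea annotation ('.apn') for record {path.name!r}"
            ) from exc
        return EcgRecord(
            record_id=path.name,
            samples=np.asarray(rec.p_signal)[:, 0],
            fs=float(rec.fs),
            minute_labels=np.array(ann.symbol),
        )
    raise ValueError(f"unknown record format {format!r}; expected 'csv' or 'wfdb'")


def write_record(record: EcgRecord, path) -> Path:
    """Write a record in the CSV dialect (signal CSV + ``.labels`` sidecar)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        {"sample_index": np.arange(len(record.samples)), "amplitude_mV": record.samples}
    )
    frame.to_csv(path, index=False)
    path.with_suffix(".labels").write_text("".join(record.minute_labels) + "\n")
    return path


# ---------------------------------------------------------------------------
# Feature-set and score-matrix persistence


def write_feature_set(path, matrices) -> Path:
    """Persist a list of feature matrices (see preprocessing.FeatureMatrix)."""
    from .preprocessing import GRID_SIZE

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    for fm in matrices:
        if fm.values.shape != (GRID_SIZE, 3):
            raise ValueError(
                f"feature matrix for {fm.record_id} minute {fm.minute_index} has shape "
                f"{fm.values.shape}, expected {(GRID_SIZE, 3)}"
            )
    n = len(matrices)
    np.savez(
        path,
        values=np.stack([fm.values for fm in matrices]) if n else np.zeros((0, GRID_SIZE, 3)),
        labels=np.array([fm.label for fm in matrices], dtype="<U1"),
        quality=np.array([fm.quality for fm in matrices], dtype="<U5"),
        record_ids=np.array([fm.record_id for fm in matrices], dtype="<U64"),
        minute_index=np.array([fm.minute_index for fm in matrices], dtype=int),
    )
    return path


def read_feature_set(path):
    """Read back a feature set written by :func:`write_feature_set`."""
    from .preprocessing import GRID_SIZE, FeatureMatrix

    with np.load(Path(path), allow_pickle=False) as data:
        values = data["values"]
        if values.ndim != 3 or values.shape[1:] != (GRID_SIZE, 3):
            raise ValueError(
                f"feature set {path} has matrix shape {values.shape[1:]}, "
                f"expected {(GRID_SIZE, 3)}"
            )
        return [
            FeatureMatrix(
                values=values[i],
                label=str(data["labels"][i]),
                quality=str(data["quality"][i]),
                record_id=str(data["record_ids"][i]),
                minute_index=int(data["minute_index"][i]),
            )
            for i in range(values.shape[0])
        ]


def write_scores(path, score_matrix) -> Path:
    """Persist a stacked ScoreMatrix (see base_models.ScoreMatrix)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path,
        probs=score_matrix.probs,
        labels=np.asarray(score_matrix.labels, dtype=int),
        model_names=np.array(score_matrix.model_names, dtype="<U64"),
    )
    return path


def read_scores(path):
    from .base_models import ScoreMatrix

    with np.load(Path(path), allow_pickle=False) as data:
        return ScoreMatrix(
            probs=data["probs"],
            labels=data["labels"],
            model_names=[str(s) for s in data["model_names"]],
        )


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """All tunables of the pipeline, serialisable to flat YAML.

    Defaults follow the study conditions: 100 Hz ECG, 1-min segments,
    240-point feature grid, Adam at 0.001 for 100 epochs with batches
    of 64, and entropy-normalised fuzzy densities.
    """

    # synthetic data
    n_minutes_per_class: int = 600
    fs: float = 100.0
    base_hr: float = 75.0
    hrv_sd: float = 0.04
    apnea_cycle_period: float = 45.0
    apnea_rr_swing: float = 0.25
    resp_rate: float = 15.0
    ramp_mod_depth: float = 0.15
    noise_sd: float = 0.03
    noisy_minute_rate: float = 0.0
    # R-peak detection
    mteo_levels: list = field(default_factory=lambda: [1, 2, 3])
    mteo_threshold_c: float = 1.0
    refractory_s: float = 0.25
    refine_window_s: float = 0.05
    # segment quality bounds
    min_beats_per_min: int = 20
    max_beats_per_min: int = 200
    rri_min_s: float = 0.3
    rri_max_s: float = 2.0
    # feature grid
    grid_size: int = 240
    median_width: int = 5
    normalization_scope: str = "train"  # train | per_fold | global
    # training
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 0.001
    seed: int = 0
    archs: list = field(
        default_factory=lambda: ["wang_cnn", "sharan_cnn", "almutairi_cnn_lstm"]
    )
    # fusion
    fusion_methods: list = field(default_factory=lambda: ["majority", "sum", "choquet", "mlp"])
    normalize_densities: bool = True
    # evaluation
    protocol: str = "holdout"  # holdout | two_fold | five_fold
    test_fraction: float = 0.25
    stratified_folds: bool = False

    def __post_init__(self):
        if self.normalization_scope not in ("train", "per_fold", "global"):
            raise ValueError(f"bad normalization_scope {self.normalization_scope!r}")
        if self.protocol not in ("holdout", "two_fold", "five_fold"):
            raise ValueError(f"bad protocol {self.protocol!r}")

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
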