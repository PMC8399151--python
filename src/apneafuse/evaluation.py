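"""Metrics, cross-validation protocols, and the end-to-end experiment.

Five classification measures are reported with apnea as the positive
class: accuracy, precision, recall, F1 (harmonic mean of the former
two) and specificity.  Zero-denominator ratios surface as NaN with a
logged note rather than silent zeros, so averages cannot be corrupted.

Two protocols mirror the study design: a two-fold swap (train on A /
test on B, then swap, average) and a shuffled five-fold CV where each
fold trains on four parts and tests on the fifth.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np

from .base_models import (
    ArchitectureSpec,
    TrainingContract,
    build_model,
    features_to_array,
    predict_proba,
    stack_scores,
    train,
)
from .fusion import fuse
from .io import RunConfig, labels_to_indices
from .preprocessing import apply_zscore, fit_zscore, preprocess_record

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CvResult",
    "confusion",
    "metrics",
    "evaluate_predictions",
    "fit_and_score",
    "two_fold_swap",
    "five_fold",
    "run_experiment",
]


@dataclass
class ConfusionCounts:
    """Binary confusion counts; positive class = apnea (class index 0)."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Count TP/TN/FP/FN with apnea as the positive class.

    Accepts labels as 0/1 class indices or 'A'/'N'/'apnea'/'normal'.
    """
    t = labels_to_indices(y_true)
    p = labels_to_indices(y_pred)
    if len(t) != len(p):
        raise ValueError("true and predicted label sequences differ in length")
    return ConfusionCounts(
        tp=int(np.sum((t == 0) & (p == 0))),
        tn=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 1) & (p == 0))),
        fn=int(np.sum((t == 0) & (p == 1))),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.info("metric %s undefined (zero denominator); reporting NaN", name)
        return float("nan")
    return num / den


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """The five ratios; NaN marks an undefined (zero-denominator) metric."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    accuracy = (counts.tp + counts.tn) / counts.total
    precision = _ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = _ratio(counts.tp, counts.tp + counts.fn, "recall")
    specificity = _ratio(counts.tn, counts.tn + counts.fp, "specificity")
    if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        specificity=specificity,
    )


def evaluate_predictions(y_true, y_pred) -> MetricsReport:
    return metrics(confusion(y_true, y_pred))


@dataclass
class CvResult:
    """Per-fold and averaged metric reports, keyed by model/ensemble name."""

    per_fold: list  # list of {name: MetricsReport}
    averaged: dict  # {name: MetricsReport}


def _average_reports(reports: list) -> dict:
    names = reports[0].keys()
    out = {}
    for name in names:
        fields = ["accuracy", "precision", "recall", "f1", "specificity"]
        means = {f: float(np.mean([getattr(r[name], f) for r in reports])) for f in fields}
        out[name] = MetricsReport(**means)
    return out


def fit_and_score(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    test_y: np.ndarray,
    config: RunConfig,
) -> dict:
    """Train the base models on one split and score every fusion method.

    Returns ``{name: MetricsReport}`` for each base architecture and each
    configured fusion rule.
    """
    if config.normalization_scope == "per_fold":
        mean = train_X.mean(axis=(0, 1))
        std = train_X.std(axis=(0, 1))
        std = np.where(std == 0, 1.0, std)
        train_X = (train_X - mean) / std
        test_X = (test_X - mean) / std
    contract = TrainingContract(
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        seed=config.seed,
    )
    train_probs, test_probs, reports = [], [], {}
    for i, name in enumerate(config.archs):
        model = build_model(ArchitectureSpec(name), seed=config.seed + i)
        train(model, train_X, train_y, contract)
        p_train = predict_proba(model, train_X)
        p_test = predict_proba(model, test_X)
        train_probs.append(p_train)
        test_probs.append(p_test)
        reports[name] = evaluate_predictions(test_y, p_test.argmax(axis=1))
    train_scores = stack_scores(train_probs, train_y, config.archs)
    test_scores = stack_scores(test_probs, test_y, config.archs)
    # the stacker is a tiny net (~200 weights); scaled-down experiments that
    # shorten CNN training would otherwise leave it with too few Adam steps,
    # so it keeps a floor of 50 epochs
    stacker_contract = dataclasses.replace(
        contract, seed=contract.seed + 1000, epochs=max(contract.epochs, 50)
    )
    for method in config.fusion_methods:
        result = fuse(
            method,
            test_scores,
            train_scores=train_scores,
            normalize_densities=config.normalize_densities,
            contract=stacker_contract,
        )
        reports[f"ensemble_{method}"] = evaluate_predictions(test_y, result.predictions)
    return reports


def _check_fold_classes(y: np.ndarray, where: str):
    if len(np.unique(y)) < 2:
        raise ValueError(f"{where} is missing a class; cannot train/evaluate")


def two_fold_swap(
    X_a: np.ndarray, y_a: np.ndarray, X_b: np.ndarray, y_b: np.ndarray, config: RunConfig
) -> CvResult:
    """Train on A / test on B, swap, and average the per-fold metrics."""
    if not len(y_a) or not len(y_b):
        raise ValueError("both folds must be nonempty")
    for y, name in ((y_a, "fold A"), (y_b, "fold B")):
        _check_fold_classes(np.asarray(y), name)
    folds = [
        fit_and_score(X_a, y_a, X_b, y_b, config),
        fit_and_score(X_b, y_b, X_a, y_a, config),
    ]
    return CvResult(per_fold=folds, averaged=_average_reports(folds))


def five_fold(X: np.ndarray, y: np.ndarray, config: RunConfig) -> CvResult:
    """Shuffled 5-fold CV: each fold trains on 4 parts, tests on 1."""
    y = np.asarray(y, dtype=int)
    for c in np.unique(y):
        if np.sum(y == c) < 5:
            raise ValueError("need at least 5 samples per class for five-fold CV")
    rng = np.random.default_rng(config.seed)
    n = len(y)
    if config.stratified_folds:
        assignment = np.empty(n, dtype=int)
        for c in np.unique(y):
            idx = np.nonzero(y == c)[0]
            idx = rng.permutation(idx)
            assignment[idx] = np.arange(len(idx)) % 5
    else:
        order = rng.permutation(n)
        assignment = np.empty(n, dtype=int)
        # contiguous fifths of the shuffled order; sizes differ by at most 1
        bounds = np.linspace(0, n, 6).astype(int)
        for f in range(5):
            assignment[order[bounds[f] : bounds[f + 1]]] = f
    folds = []
    for f in range(5):
        test_mask = assignment == f
        _check_fold_classes(y[~test_mask], f"five-fold training split {f}")
        _check_fold_classes(y[test_mask], f"five-fold test split {f}")
        folds.append(
            fit_and_score(X[~test_mask], y[~test_mask], X[test_mask], y[test_mask], config)
        )
    return CvResult(per_fold=folds, averaged=_average_reports(folds))


def fold_assignment(n: int, seed: int) -> np.ndarray:
    """The (unstratified) 5-fold split assignment used by :func:`five_fold`."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    bounds = np.linspace(0, n, 6).astype(int)
    for f in range(5):
        assignment[order[bounds[f] : bounds[f + 1]]] = f
    return assignment


def _synthetic_features(config: RunConfig, seed: int, record_id: str):
    """Generate a synthetic record per config and preprocess it to features."""
    from .synthetic import SyntheticSpec, generate_record

    spec = SyntheticSpec(
        n_minutes_per_class=config.n_minutes_per_class,
        fs=config.fs,
        base_hr=config.base_hr,
        hrv_sd=config.hrv_sd,
        apnea_cycle_period=config.apnea_cycle_period,
        apnea_rr_swing=config.apnea_rr_swing,
        resp_rate=config.resp_rate,
        ramp_mod_depth=config.ramp_mod_depth,
        noise_sd=config.noise_sd,
        noisy_minute_rate=config.noisy_minute_rate,
        seed=seed,
        record_id=record_id,
    )
    return preprocess_record(generate_record(spec), config)


def run_experiment(config: RunConfig, feature_sets: dict | None = None) -> dict:
    """End-to-end experiment: data → features → base models → fusion → table.

    ``feature_sets`` may supply preprocessed ``{"train": [...], "test":
    [...]}`` FeatureMatrix lists; otherwise synthetic data is generated
    from the config.  Returns a JSON-ready report whose ``table`` maps
    each of the 3 base models and the configured ensembles to the five
    metrics.
    """
    if feature_sets is None:
        train_fms = _synthetic_features(config, config.seed, "synthetic-train")
        test_fms = _synthetic_features(config, config.seed + 1, "synthetic-test")
    else:
        if "train" not in feature_sets or "test" not in feature_sets:
            raise ValueError("feature_sets must provide 'train' and 'test' lists")
        train_fms, test_fms = feature_sets["train"], feature_sets["test"]
    if not train_fms or not test_fms:
        raise ValueError("no data available: supply feature sets or a synthetic config")

    if config.normalization_scope == "per_fold":
        # normalisation happens inside each training fold (fit_and_score)
        train_X, train_y = features_to_array(train_fms)
        test_X, test_y = features_to_array(test_fms)
    else:
        stats = fit_zscore(
            train_fms if config.normalization_scope == "train" else train_fms + test_fms
        )
        train_X, train_y = features_to_array([apply_zscore(fm, stats) for fm in train_fms])
        test_X, test_y = features_to_array([apply_zscore(fm, stats) for fm in test_fms])

    if config.protocol == "holdout":
        reports = fit_and_score(train_X, train_y, test_X, test_y, config)
        result = CvResult(per_fold=[reports], averaged=reports)
    elif config.protocol == "two_fold":
        result = two_fold_swap(train_X, train_y, test_X, test_y, config)
    else:
        X = np.concatenate([train_X, test_X])
        y = np.concatenate([train_y, test_y])
        result = five_fold(X, y, config)

    return {
        "protocol": config.protocol,
        "n_train": int(len(train_y)),
        "n_test": int(len(test_y)),
        "table": {name: r.as_dict() for name, r in result.averaged.items()},
        "per_fold": [
            {name: r.as_dict() for name, r in fold.items()} for fold in result.per_fold
        ],
    }


def render_table(report: dict) -> str:
    """Plain-text metric table (rows: models/ensembles; columns: 5 metrics)."""
    cols = ["accuracy", "precision", "recall", "f1", "specificity"]
    width = max(len(n) for n in report["table"]) + 2
    lines = ["".join([" " * width] + [f"{c:>12}" for c in cols])]
    for name, row in report["table"].items():
        cells = "".join(f"{row[c] * 100:11.2f}%" for c in cols)
        lines.append(f"{name:<{width}}" + cells)
    return "\n".join(lines)
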