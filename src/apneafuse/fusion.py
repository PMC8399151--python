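"""Classifier fusion: majority vote, sum rule, Choquet fuzzy fusion, MLP stacker.

The Choquet route is the heart of the package.  Per sample, each base
classifier m_j gets a confidence density g_j = 1 − E_j, where E_j is the
base-2 Shannon entropy of its probability vector (so the density is 0
for a maximally uncertain classifier and 1 for a fully confident one).
With ``normalize_densities`` the densities are divided by their sum —
then they add to 1, the Sugeno λ-measure is additive (λ = 0) and the
Choquet integral reduces to an entropy-weighted mean; without it the
raw densities induce a genuinely non-additive measure.  λ is the unique
root > −1 of

    1 + λ = ∏_j (1 + λ·g_j),  λ ≠ 0 unless Σ g_j = 1,

and subsets grow by the Sugeno union rule
g(A ∪ {m}) = g(A) + g_m + λ·g(A)·g_m, which makes g(X) = 1 exactly.
Per class, scores are sorted decreasingly and integrated against the
increments of the measure (the Choquet integral); the fused prediction
is the arg-max class.

Tie-breaking is deterministic everywhere: lowest class index, lowest
classifier index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import nnkit
from .base_models import ScoreMatrix, TrainingContract

__all__ = [
    "FuzzyMeasure",
    "FusionResult",
    "entropy",
    "singleton_measures",
    "solve_lambda",
    "measure_of_subset",
    "choquet_fuse",
    "majority_vote",
    "sum_rule",
    "MlpStacker",
    "fuse",
]


@dataclass
class FusionResult:
    """Fused class scores and hard predictions for a batch of samples."""

    scores: np.ndarray  # (n, k)
    predictions: np.ndarray  # (n,)
    method: str

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.predictions = np.asarray(self.predictions, dtype=int)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("fused scores must be finite")


@dataclass
class FuzzyMeasure:
    """A Sugeno λ-measure over the classifier set, given singleton densities."""

    densities: np.ndarray
    lam: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.densities = np.asarray(self.densities, dtype=float)
        if self.lam is None:
            self.lam = solve_lambda(self.densities)

    def __call__(self, subset) -> float:
        return measure_of_subset(subset, self.densities, self.lam)


def _check_simplex(p: np.ndarray, atol: float = 1e-6):
    if np.any(p < -1e-12):
        raise ValueError("probability vector has a negative component")
    if np.any(np.abs(p.sum(axis=-1) - 1.0) > atol):
        raise ValueError("probability rows must sum to 1")


def entropy(p) -> float:
    """Base-2 Shannon entropy of a probability vector, with 0·log0 := 0.

    For two classes the maximum is 1, attained at the uniform vector.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probability vector has a negative component")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _entropies(probs: np.ndarray) -> np.ndarray:
    """Row-wise base-2 entropy over the trailing axis."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(probs > 0, probs * np.log2(np.where(probs > 0, probs, 1.0)), 0.0)
    return -terms.sum(axis=-1)


def singleton_measures(sample_scores: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Per-classifier confidence densities g_j from one sample's l×k scores.

    g_j = 1 − E_j (entropy complement), normalised to sum to 1 when
    ``normalize``; if every classifier is maximally uncertain the
    uniform fallback g_j = 1/l is used.
    """
    scores = np.asarray(sample_scores, dtype=float)
    _check_simplex(scores)
    l, k = scores.shape
    max_e = np.log2(k)  # 1 bit for two classes
    raw = 1.0 - _entropies(scores) / max_e
    raw = np.clip(raw, 0.0, None)
    if normalize:
        total = raw.sum()
        if total <= 0:
            return np.full(l, 1.0 / l)
        return raw / total
    if raw.sum() <= 0:
        return np.full(l, 1.0 / l)
    return raw


def solve_lambda(densities) -> float:
    """Solve 1 + λ = ∏_j (1 + λ·g_j) for the unique admissible λ > −1.

    λ = 0 when the densities sum to 1 (additive measure); otherwise the
    root is positive when Σg < 1 and lies in (−1, 0) when Σg > 1.
    """
    g = np.asarray(densities, dtype=float)
    if np.any((g < 0) | (g > 1)):
        raise ValueError("densities must lie in [0, 1]")
    # densities below 1e-9 carry no information but would push the root
    # beyond floating-point range; treat them as zero
    active = g[g > 1e-9]
    if active.size <= 1:
        # at most one informative classifier: the union rule never fires,
        # so the measure is additive regardless of lambda
        return 0.0
    total = active.sum()
    if abs(total - 1.0) <= 1e-9:
        return 0.0

    def f(lam):
        # log form of prod(1 + lam*g) - (1 + lam): same sign and roots,
        # but immune to the cancellation that ruins the product form near 0
        return np.log1p(lam * active).sum() - np.log1p(lam)

    if total < 1.0:
        lo = 1e-15
        hi = 1.0
        while f(hi) <= 0:
            hi *= 2.0
            if hi > 1e300:  # pragma: no cover - defensive
                raise RuntimeError("failed to bracket lambda root")
        root = float(brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=500))
    else:
        hi = -1e-12
        lo = None
        for q in range(1, 16):
            cand = -1.0 + 10.0 ** (-q)
            if f(cand) > 0:
                lo = cand
                break
        if lo is None:
            # a density at (or within machine precision of) 1 drives the
            # root to its -1 limit; the nearest representable value keeps
            # the normalisation error far below 1e-8
            root = -1.0 + 1e-15
        else:
            root = float(brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=500))
    # normalisation invariant: folding every density must give g(X) = 1
    gx = 0.0
    for d in g:
        gx = gx + d + root * gx * d
    if abs(gx - 1.0) > 1e-8:  # pragma: no cover - solver failure guard
        raise RuntimeError(f"lambda solve failed: g(X) = {gx!r}")
    return root


def measure_of_subset(subset, densities, lam: float) -> float:
    """Sugeno measure of a classifier subset by folding the union rule.

    The fold g ← g + g_m + λ·g·g_m is associative and commutative, so
    the result is order-independent; the empty set has measure 0.
    """
    g = np.asarray(densities, dtype=float)
    total = 0.0
    seen = set()
    for j in subset:
        if j < 0 or j >= len(g):
            raise ValueError(f"classifier index {j} outside the ensemble of {len(g)}")
        if j in seen:
            raise ValueError(f"duplicate classifier index {j} in subset")
        seen.add(j)
        total = total + g[j] + lam * total * g[j]
    return float(total)


def _choquet_sample(scores: np.ndarray, normalize: bool) -> np.ndarray:
    """Fused class scores for one sample's (l, k) probability block."""
    l, k = scores.shape
    g = singleton_measures(scores, normalize=normalize)
    lam = solve_lambda(g)
    out = np.empty(k)
    for i in range(k):
        s = scores[:, i]
        # decreasing scores; ties broken by classifier index
        order = np.lexsort((np.arange(l), -s))
        prev = 0.0
        total = 0.0
        acc = 0.0
        for j in order:
            acc = acc + g[j] + lam * acc * g[j]
            total += s[j] * (acc - prev)
            prev = acc
        out[i] = total
    return out


def choquet_fuse(probs: np.ndarray, normalize: bool = True) -> FusionResult:
    """Choquet-integral fusion with per-sample entropy-derived λ-measures.

    ``probs`` is (n, l, k) or a single (l, k) block.  The measure is
    computed from each sample's own probability vectors, so confident
    classifiers get more weight sample by sample.
    """
    probs = np.asarray(probs, dtype=float)
    single = probs.ndim == 2
    if single:
        probs = probs[None]
    scores = np.stack([_choquet_sample(block, normalize) for block in probs])
    preds = scores.argmax(axis=1)
    return FusionResult(scores=scores, predictions=preds, method="choquet")


def sum_rule(probs: np.ndarray) -> FusionResult:
    """Score-level fusion: CS_i = Σ_j p_ij, arg-max class wins.

    Ties resolve toward the lower class index.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim == 2:
        probs = probs[None]
    if not np.all(np.isfinite(probs)):
        raise ValueError("scores must be finite")
    _check_simplex(probs)
    scores = probs.sum(axis=1)
    return FusionResult(scores=scores, predictions=scores.argmax(axis=1), method="sum")


def majority_vote(probs: np.ndarray) -> FusionResult:
    """Decision-level fusion: each classifier votes its arg-max class.

    Vote ties are broken by the sum rule on the accompanying scores
    (impossible for 3 classifiers and 2 classes).
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim == 2:
        probs = probs[None]
    n, l, k = probs.shape
    if l < 1 or n < 1:
        raise ValueError("majority vote needs at least one classifier and one sample")
    hard = probs.argmax(axis=2)  # (n, l)
    counts = np.zeros((n, k))
    for i in range(k):
        counts[:, i] = (hard == i).sum(axis=1)
    top = counts.max(axis=1, keepdims=True)
    tied = (counts == top).sum(axis=1) > 1
    preds = counts.argmax(axis=1)
    if np.any(tied):
        preds[tied] = sum_rule(probs[tied]).predictions
    return FusionResult(scores=counts, predictions=preds, method="majority")


class MlpStacker:
    """Trainable ensemble: a one-hidden-layer MLP over flattened scores.

    The net takes the k·l concatenated class scores of the base models,
    passes them through a 16-unit ReLU hidden layer, and emits k softmax
    scores; it is trained with the same Adam/cross-entropy contract as
    the base models.
    """

    def __init__(self, hidden: int = 16):
        self.hidden = hidden
        self._model: nnkit.Sequential | None = None
        self._in_dim: int | None = None
        self._k: int | None = None

    def fit(self, scores: ScoreMatrix | np.ndarray, labels=None,
            contract: TrainingContract = TrainingContract()) -> list[dict]:
        probs, y = _scores_and_labels(scores, labels)
        n, l, k = probs.shape
        rng = np.random.default_rng(contract.seed)
        self._in_dim = l * k
        self._k = k
        self._model = nnkit.Sequential(
            [
                nnkit.Dense(self._in_dim, self.hidden, rng),
                nnkit.ReLU(),
                nnkit.Dense(self.hidden, k, rng),
            ],
            seed=contract.seed,
        )
        return self._model.fit(
            probs.reshape(n, -1),
            y,
            epochs=contract.epochs,
            batch_size=contract.batch_size,
            lr=contract.learning_rate,
            rng=np.random.default_rng(contract.seed + 1),
        )

    def predict(self, scores: ScoreMatrix | np.ndarray) -> FusionResult:
        if self._model is None:
            raise RuntimeError("MlpStacker.predict called before fit")
        probs = scores.probs if isinstance(scores, ScoreMatrix) else np.asarray(scores, float)
        n = probs.shape[0]
        flat = probs.reshape(n, -1)
        if flat.shape[1] != self._in_dim:
            raise ValueError(
                f"score feature dimension {flat.shape[1]} != fitted {self._in_dim}"
            )
        fused = self._model.predict_proba(flat)
        return FusionResult(scores=fused, predictions=fused.argmax(axis=1), method="mlp")


def _scores_and_labels(scores, labels):
    if isinstance(scores, ScoreMatrix):
        return scores.probs, scores.labels
    probs = np.asarray(scores, dtype=float)
    if labels is None:
        raise ValueError("labels required when passing a raw probability array")
    return probs, np.asarray(labels, dtype=int)


def fuse(
    method: str,
    test_scores: ScoreMatrix,
    train_scores: ScoreMatrix | None = None,
    normalize_densities: bool = True,
    contract: TrainingContract = TrainingContract(),
) -> FusionResult:
    """Dispatch one of the four fusion rules on a test ScoreMatrix."""
    if method == "majority":
        return majority_vote(test_scores.probs)
    if method == "sum":
        return sum_rule(test_scores.probs)
    if method == "choquet":
        return choquet_fuse(test_scores.probs, normalize=normalize_densities)
    if method == "mlp":
        if train_scores is None:
            raise ValueError("the MLP stacker needs training scores")
        stacker = MlpStacker()
        stacker.fit(train_scores, contract=contract)
        return stacker.predict(test_scores)
    raise ValueError(f"unknown fusion method {method!r}")
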