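"""Synthetic labelled ECG and score-matrix generators.

The record generator emulates the statistical structure the detection
pipeline relies on, not ECG morphology: a fixed QRS-like template
(Mexican-hat pulse, ~0.1 s wide) placed at beat times, respiratory
amplitude modulation of the R peaks, and class-dependent RR dynamics —
stationary heart-rate variability for normal minutes versus the cyclic
bradycardia/tachycardia oscillation (period tens of seconds) that
accompanies obstructive apnea episodes.  A configurable fraction of
minutes is replaced by high-amplitude broadband noise to exercise the
quality filter.

The score-matrix generator fabricates base-classifier probability
outputs with controlled per-classifier accuracy and sharpness, which is
the harness every fusion rule is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import EcgRecord

__all__ = [
    "SyntheticSpec",
    "BeatTruth",
    "generate_record",
    "generate_record_with_truth",
    "generate_score_matrices",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic ECG generator.

    ``apnea_rr_swing`` is the fractional depth of the cyclic RR
    modulation in apnea minutes; ``apnea_cycle_period`` its period in
    seconds (45 s sits in the 30–60 s band of the cyclical
    variation-of-heart-rate phenomenon).  ``noisy_minute_rate`` is the
    probability that a minute is replaced by broadband noise while
    keeping its class label.
    """

    n_minutes_per_class: int = 30
    fs: float = 100.0
    base_hr: float = 75.0
    hrv_sd: float = 0.04
    apnea_cycle_period: float = 45.0
    apnea_rr_swing: float = 0.25
    resp_rate: float = 15.0
    ramp_mod_depth: float = 0.15
    noise_sd: float = 0.03
    noisy_minute_rate: float = 0.0
    seed: int = 0
    record_id: str = "synthetic"

    def __post_init__(self):
        if not 0 < self.apnea_rr_swing < 1:
            raise ValueError("apnea_rr_swing must lie in (0, 1)")
        if not 0 <= self.noisy_minute_rate <= 1:
            raise ValueError("noisy_minute_rate must lie in [0, 1]")
        if self.fs <= 0 or self.base_hr <= 0:
            raise ValueError("fs and base_hr must be positive")


@dataclass
class BeatTruth:
    """Ground truth accompanying a generated record (for detector oracles)."""

    beat_samples: np.ndarray  # sample index of every placed template centre
    beat_amplitudes: np.ndarray
    noisy_minutes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def qrs_template(fs: float, width_s: float = 0.1, sigma_s: float = 0.018) -> np.ndarray:
    """Mexican-hat (Ricker) pulse of total width ``width_s``, unit peak."""
    half = int(round(width_s / 2 * fs))
    t = np.arange(-half, half + 1) / fs
    x = (1 - (t / sigma_s) ** 2) * np.exp(-(t**2) / (2 * sigma_s**2))
    return x


def _minute_order(n_per_class: int, rng: np.random.Generator) -> np.ndarray:
    """Interleave apnea/normal minutes in a shuffled order (0=apnea, 1=normal)."""
    order = np.array([0] * n_per_class + [1] * n_per_class)
    rng.shuffle(order)
    return order


def generate_record_with_truth(spec: SyntheticSpec) -> tuple[EcgRecord, BeatTruth]:
    """Generate a record plus the ground-truth beat placements."""
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    spm = int(round(60 * fs))
    classes = _minute_order(spec.n_minutes_per_class, rng)
    n_minutes = len(classes)
    total = n_minutes * spm
    signal = np.zeros(total)

    base_rr = 60.0 / spec.base_hr
    template = qrs_template(fs)
    half = len(template) // 2

    beat_samples: list[int] = []
    beat_amps: list[float] = []
    # Beat-time processes restart each minute so every minute is
    # self-contained (labels are per-minute); the apnea oscillation phase
    # is tied to absolute time so the cycle spans consecutive minutes.
    for m, cls in enumerate(classes):
        t = m * 60.0
        end = (m + 1) * 60.0
        while True:
            rr = base_rr + rng.normal(0.0, spec.hrv_sd) if spec.hrv_sd > 0 else base_rr
            rr = max(rr, 0.2)
            if cls == 0:  # apnea: cyclic RR modulation
                rr *= 1.0 + spec.apnea_rr_swing * np.sin(
                    2 * np.pi * t / spec.apnea_cycle_period
                )
            if t >= end:
                break
            amp = 1.0 + spec.ramp_mod_depth * np.sin(2 * np.pi * t * spec.resp_rate / 60.0)
            idx = int(round(t * fs))
            if idx >= (m + 1) * spm:
                # rounding pushed this beat onto the next minute's first
                # sample, where that minute restarts its own beat train
                break
            lo = max(idx - half, 0)
            hi = min(idx + half + 1, total)
            signal[lo:hi] += amp * template[lo - (idx - half) : hi - (idx - half)]
            beat_samples.append(idx)
            beat_amps.append(amp)
            t += rr

    if spec.noise_sd > 0:
        signal += rng.normal(0.0, spec.noise_sd, size=total)

    noisy = []
    if spec.noisy_minute_rate > 0:
        for m in range(n_minutes):
            if rng.random() < spec.noisy_minute_rate:
                signal[m * spm : (m + 1) * spm] = rng.normal(0.0, 3.0, size=spm)
                noisy.append(m)
    noisy_arr = np.array(noisy, dtype=int)

    beats = np.array(beat_samples, dtype=int)
    keep = ~np.isin(beats // spm, noisy_arr) if len(noisy) else np.ones(len(beats), bool)
    truth = BeatTruth(
        beat_samples=beats[keep],
        beat_amplitudes=np.array(beat_amps)[keep],
        noisy_minutes=noisy_arr,
    )
    record = EcgRecord(
        record_id=spec.record_id,
        samples=signal,
        fs=fs,
        minute_labels=np.array(["AN"[c] for c in classes]),
    )
    return record, truth


def generate_record(spec: SyntheticSpec) -> EcgRecord:
    """Generate a labelled synthetic ECG record (deterministic per seed)."""
    record, _ = generate_record_with_truth(spec)
    return record


def generate_score_matrices(
    n_samples: int,
    l: int,
    k: int,
    accuracies,
    sharpness: float = 12.0,
    seed: int = 0,
):
    """Fabricate base-classifier probability outputs with known accuracy.

    For each sample and classifier ``j`` the probability mass concentrates
    (Dirichlet draw, concentration ``sharpness`` on the target component)
    on the true class with probability ``accuracies[j]``, otherwise on a
    uniformly chosen wrong class.  ``sharpness=np.inf`` yields one-hot rows.

    Returns ``(probs, labels)`` with ``probs`` of shape (n_samples, l, k)
    and integer ``labels`` of shape (n_samples,).
    """
    accuracies = np.asarray(accuracies, dtype=float)
    if accuracies.shape != (l,):
        raise ValueError(f"need one accuracy per classifier, got {accuracies.shape}")
    if np.any(accuracies <= 1.0 / k) or np.any(accuracies > 1.0):
        raise ValueError(f"accuracies must lie in (1/k, 1] = ({1.0/k:.3f}, 1]")
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, k, size=n_samples)
    probs = np.empty((n_samples, l, k))
    for j in range(l):
        correct = rng.random(n_samples) < accuracies[j]
        offsets = rng.integers(1, k, size=n_samples)
        targets = np.where(correct, labels, (labels + offsets) % k)
        if np.isinf(sharpness):
            rows = np.zeros((n_samples, k))
            rows[np.arange(n_samples), targets] = 1.0
        else:
            alpha = np.ones((n_samples, k))
            alpha[np.arange(n_samples), targets] += sharpness
            # Dirichlet via normalised gammas (vectorised over samples)
            g = rng.gamma(shape=alpha)
            rows = g / g.sum(axis=1, keepdims=True)
        probs[:, j, :] = rows
    return probs, labels
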