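"""Raw ECG → per-minute 240×3 feature matrices.

Pipeline per labelled minute (6000 samples at 100 Hz):

1. R-peak localisation with a Multilevel Teager Energy Operator (MTEO):
   for each level ``k`` the nonlinear energy ψ_k[n] = x[n]² − x[n−k]·x[n+k]
   is smoothed with a tapered (Hamming) window of length 4k+1, the levels
   are combined by an elementwise maximum, and peaks are local maxima of
   the combined energy above mean + c·std, thinned by a refractory
   interval (larger energy wins) and refined to the argmax of |signal|
   within ±50 ms.
2. Beat-indexed series: RR intervals (s), R-peak amplitudes relative to
   the segment mean (RAMP), and a respiration surrogate (EDR) taken as
   the rectified QRS area in a ±50 ms window around each peak.
3. Quality gate on the beat series (rate and RRI plausibility bounds) —
   segments failing it are flagged ``noise`` and excluded from training.
4. Median filtering (ectopic suppression) and natural cubic-spline
   interpolation of the three series onto a uniform 240-point grid over
   the minute (one point per 0.25 s), holding boundary values outside
   the first/last beat.
5. Z-score normalisation per feature column, with statistics fitted on a
   designated fitting set (train split by default) to avoid leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import medfilt

from .io import EcgRecord, RunConfig

logger = logging.getLogger(__name__)

#: Number of grid points per minute in a feature matrix (0.25 s spacing).
GRID_SIZE = 240
#: Samples per 1-min segment at the native 100 Hz rate.
SEGMENT_SAMPLES = 6000

__all__ = [
    "GRID_SIZE",
    "SEGMENT_SAMPLES",
    "Segment",
    "BeatSeries",
    "FeatureMatrix",
    "NormalizationStats",
    "segment_record",
    "mteo_detect",
    "extract_beat_series",
    "classify_quality",
    "resample_features",
    "fit_zscore",
    "apply_zscore",
    "preprocess_record",
]


@dataclass
class Segment:
    """One labelled minute of ECG (6000 samples at 100 Hz)."""

    record_id: str
    minute_index: int
    samples: np.ndarray
    label: str  # 'A' or 'N'
    fs: float = 100.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        expected = int(round(60 * self.fs))
        if len(self.samples) != expected:
            raise ValueError(
                f"segment must hold one full minute ({expected} samples at "
                f"{self.fs} Hz), got {len(self.samples)}"
            )


@dataclass
class BeatSeries:
    """Beat-indexed features of a segment: RR intervals, amplitudes, EDR."""

    r_indices: np.ndarray
    rri: np.ndarray  # seconds, length len(r_indices) - 1
    ramp: np.ndarray  # mV relative to segment mean, per beat
    edr: np.ndarray  # rectified QRS area per beat
    fs: float = 100.0

    def __post_init__(self):
        self.r_indices = np.asarray(self.r_indices, dtype=int)
        if len(self.r_indices) >= 2:
            if np.any(np.diff(self.r_indices) <= 0):
                raise ValueError("r_indices must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return len(self.r_indices)

    @property
    def empty(self) -> bool:
        return self.n_beats < 2


@dataclass
class FeatureMatrix:
    """240×3 per-minute feature matrix (columns: RRI, RAMP, EDR)."""

    values: np.ndarray
    label: str
    quality: str  # 'clear' or 'noise'
    record_id: str
    minute_index: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (GRID_SIZE, 3):
            raise ValueError(f"feature matrix must be {GRID_SIZE}×3, got {self.values.shape}")
        if self.quality not in ("clear", "noise"):
            raise ValueError(f"quality must be 'clear' or 'noise', got {self.quality!r}")
        if self.quality == "clear" and not np.all(np.isfinite(self.values)):
            raise ValueError("clear feature matrix must be finite")


@dataclass
class NormalizationStats:
    """Per-column mean/sd of a fitting set, for z-score normalisation."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if np.any(self.std < 0):
            raise ValueError("standard deviations must be non-negative")


def segment_record(record: EcgRecord) -> list[Segment]:
    """Split a record into labelled 1-min segments; partial minutes dropped."""
    if round(record.fs) != 100:
        raise ValueError(
            f"record {record.record_id!r} sampled at {record.fs} Hz; resample to "
            "100 Hz before segmentation"
        )
    segments = []
    for m in range(record.n_full_minutes):
        lo, hi = record.minute_window(m)
        segments.append(
            Segment(
                record_id=record.record_id,
                minute_index=m,
                samples=record.samples[lo:hi],
                label=record.minute_labels[m],
                fs=record.fs,
            )
        )
    return segments


def _teager_multi(x: np.ndarray, levels) -> np.ndarray:
    """Combined multilevel Teager energy: smoothed ψ_k, max over levels."""
    n = len(x)
    combined = np.full(n, -np.inf)
    for k in levels:
        psi = np.zeros(n)
        if n > 2 * k:
            psi[k:-k] = x[k:-k] ** 2 - x[:-2 * k] * x[2 * k:]
        win = np.hamming(4 * k + 1)
        win /= win.sum()
        smooth = np.convolve(psi, win, mode="same")
        combined = np.maximum(combined, smooth)
    return combined


def mteo_detect(
    segment: Segment,
    levels=(1, 2, 3),
    threshold_c: float = 1.0,
    refractory_s: float = 0.25,
    refine_window_s: float = 0.05,
) -> np.ndarray:
    """Locate R peaks in a segment; returns sorted sample indices.

    A flat or empty-energy segment yields an empty array rather than an
    exception.
    """
    if not len(levels):
        raise ValueError("levels must be nonempty")
    if refractory_s <= 0:
        raise ValueError("refractory interval must be positive")
    x = segment.samples - segment.samples.mean()
    energy = _teager_multi(x, levels)
    std = energy.std()
    if std == 0:
        return np.array([], dtype=int)
    thr = energy.mean() + threshold_c * std
    interior = np.arange(1, len(energy) - 1)
    is_peak = (
        (energy[interior] > energy[interior - 1])
        & (energy[interior] >= energy[interior + 1])
        & (energy[interior] > thr)
    )
    candidates = interior[is_peak]
    if not len(candidates):
        return np.array([], dtype=int)

    # refractory thinning: greedily keep the larger-energy peak
    refractory = int(round(refractory_s * segment.fs))
    order = candidates[np.argsort(energy[candidates])[::-1]]
    kept: list[int] = []
    for idx in order:
        if all(abs(idx - other) >= refractory for other in kept):
            kept.append(int(idx))

    # refine to the absolute-amplitude maximum within +/- the refine window
    half = int(round(refine_window_s * segment.fs))
    refined = set()
    for idx in kept:
        lo = max(idx - half, 0)
        hi = min(idx + half + 1, len(x))
        refined.add(lo + int(np.argmax(np.abs(x[lo:hi]))))
    return np.array(sorted(refined), dtype=int)


def extract_beat_series(segment: Segment, r_indices) -> BeatSeries:
    """Derive RRI/RAMP/EDR from detected R peaks.

    With fewer than two peaks the series is returned empty; downstream
    quality classification then marks the segment as noise.
    """
    r_indices = np.asarray(r_indices, dtype=int)
    fs = segment.fs
    if len(r_indices) < 2:
        return BeatSeries(
            r_indices=r_indices,
            rri=np.array([]),
            ramp=np.array([]),
            edr=np.array([]),
            fs=fs,
        )
    x = segment.samples - segment.samples.mean()
    rri = np.diff(r_indices) / fs
    ramp = x[r_indices]
    half = int(round(0.05 * fs))
    edr = np.array(
        [
            np.abs(x[max(i - half, 0) : min(i + half + 1, len(x))]).sum() / fs
            for i in r_indices
        ]
    )
    return BeatSeries(r_indices=r_indices, rri=rri, ramp=ramp, edr=edr, fs=fs)


def classify_quality(
    beats: BeatSeries,
    min_beats: int = 20,
    max_beats: int = 200,
    rri_min: float = 0.3,
    rri_max: float = 2.0,
) -> str:
    """Physiological-plausibility gate: 'clear' or 'noise'.

    A minute is noise when its beat count falls outside [min_beats,
    max_beats] or any raw RR interval falls outside [rri_min, rri_max]
    seconds.
    """
    if beats.n_beats < min_beats or beats.n_beats > max_beats:
        return "noise"
    if len(beats.rri) and (np.any(beats.rri < rri_min) or np.any(beats.rri > rri_max)):
        return "noise"
    return "clear"


def _median_smooth(series: np.ndarray, width: int) -> np.ndarray:
    if width <= 1 or len(series) < 3:
        return series
    w = min(width, len(series))
    if w % 2 == 0:
        w -= 1
    return medfilt(series, kernel_size=w) if w >= 3 else series


def _spline_to_grid(times: np.ndarray, values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Natural cubic spline; boundary values held outside [t_first, t_last]."""
    spline = CubicSpline(times, values, bc_type="natural")
    clamped = np.clip(grid, times[0], times[-1])
    return spline(clamped)


def resample_features(
    beats: BeatSeries,
    segment: Segment,
    grid_size: int = GRID_SIZE,
    median_width: int = 5,
) -> FeatureMatrix:
    """Interpolate the beat series onto the uniform per-minute grid.

    RRI and RAMP are median-filtered first; RR intervals sit at the
    midpoint of their two beats, RAMP/EDR at the beat time.  Segments
    with too few beats for spline fitting are reclassified as noise.
    """
    fs = segment.fs
    grid = np.arange(grid_size) * (60.0 / grid_size)
    if beats.n_beats < 4:
        return FeatureMatrix(
            values=np.full((grid_size, 3), np.nan),
            label=segment.label,
            quality="noise",
            record_id=segment.record_id,
            minute_index=segment.minute_index,
        )
    beat_times = beats.r_indices / fs
    rri_times = (beat_times[:-1] + beat_times[1:]) / 2.0
    rri = _median_smooth(beats.rri, median_width)
    ramp = _median_smooth(beats.ramp, median_width)
    cols = np.column_stack(
        [
            _spline_to_grid(rri_times, rri, grid),
            _spline_to_grid(beat_times, ramp, grid),
            _spline_to_grid(beat_times, beats.edr, grid),
        ]
    )
    return FeatureMatrix(
        values=cols,
        label=segment.label,
        quality="clear",
        record_id=segment.record_id,
        minute_index=segment.minute_index,
    )


def fit_zscore(matrices) -> NormalizationStats:
    """Pooled per-column mean/sd over the clear matrices of a fitting set."""
    clear = [fm.values for fm in matrices if fm.quality == "clear"]
    if not clear:
        raise ValueError("z-score fitting set must contain at least one clear matrix")
    stacked = np.concatenate(clear, axis=0)
    mean = stacked.mean(axis=0)
    std = stacked.std(axis=0)
    if np.any(std == 0):
        logger.warning(
            "constant feature column(s) %s in fitting set; normalised to zeros",
            np.nonzero(std == 0)[0].tolist(),
        )
    return NormalizationStats(mean=mean, std=std)


def apply_zscore(matrix: FeatureMatrix, stats: NormalizationStats) -> FeatureMatrix:
    """Return a new matrix with each column z-scored by the fitted stats."""
    safe_std = np.where(stats.std == 0, 1.0, stats.std)
    values = (matrix.values - stats.mean) / safe_std
    values[:, stats.std == 0] = 0.0
    return FeatureMatrix(
        values=values,
        label=matrix.label,
        quality=matrix.quality,
        record_id=matrix.record_id,
        minute_index=matrix.minute_index,
    )


def preprocess_record(record: EcgRecord, config: RunConfig | None = None) -> list[FeatureMatrix]:
    """Full per-record pipeline: segment → detect → features → quality → grid.

    Returns one FeatureMatrix per labelled full minute (noise minutes
    carry NaN values and quality='noise').  Z-scoring is applied
    separately so statistics can be fitted on the training split only.
    """
    cfg = config or RunConfig()
    out = []
    n_noise = 0
    for segment in segment_record(record):
        r_idx = mteo_detect(
            segment,
            levels=tuple(cfg.mteo_levels),
            threshold_c=cfg.mteo_threshold_c,
            refractory_s=cfg.refractory_s,
            refine_window_s=cfg.refine_window_s,
        )
        beats = extract_beat_series(segment, r_idx)
        quality = classify_quality(
            beats,
            min_beats=cfg.min_beats_per_min,
            max_beats=cfg.max_beats_per_min,
            rri_min=cfg.rri_min_s,
            rri_max=cfg.rri_max_s,
        )
        if quality == "noise":
            n_noise += 1
            out.append(
                FeatureMatrix(
                    values=np.full((cfg.grid_size, 3), np.nan),
                    label=segment.label,
                    quality="noise",
                    record_id=segment.record_id,
                    minute_index=segment.minute_index,
                )
            )
            continue
        out.append(
            resample_features(
                beats, segment, grid_size=cfg.grid_size, median_width=cfg.median_width
            )
        )
    logger.info(
        "record %s: %d clear / %d noise minutes",
        record.record_id,
        len(out) - n_noise,
        n_noise,
    )
    return out
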