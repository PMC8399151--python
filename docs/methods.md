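# Methods

This note documents the models, the synthetic data, the numerical
choices and the known limitations of `apneafuse`.

## Problem and data model

The unit of classification is one minute of single-lead ECG sampled at
100 Hz (6000 samples), labelled apnea (`A`) or normal (`N`).  Apnea is
the positive class throughout; minute `m` covers the half-open sample
window `[6000·m, 6000·(m+1))` with 0-based indices, and a trailing
partial minute is dropped rather than padded (only full 1-min segments
are used).

Records are read either from a PhysioNet-style WFDB signal/annotation
pair (optional `wfdb` dependency) or from a plain CSV dialect
(`sample_index,amplitude_mV` plus a `.labels` sidecar with one `A`/`N`
character per minute).  The supplied train/test membership is the
user's responsibility; nothing in the package hard-codes a record
split.

## Pre-processing

**R-peak detection.**  A multilevel Teager energy operator: for levels
k ∈ {1, 2, 3} the nonlinear energy ψ_k[n] = x[n]² − x[n−k]·x[n+k]
(zero at the k boundary samples) is smoothed with a normalised Hamming
window of length 4k+1 and the levels are combined with an elementwise
maximum.  Candidate peaks are local maxima of the combined energy above
`mean + c·std`; a 250 ms refractory interval keeps the larger-energy
candidate, and each survivor is refined to the argmax of |mean-removed
signal| within ±50 ms.  The threshold constant defaults to `c = 1`:
the energy trace is sparse and spiky, so its standard deviation is
dominated by the QRS complexes themselves, and larger multipliers
discard genuine beats (at `c = 4` roughly half the beats of a clean
synthetic record are lost; at `c = 1` sensitivity and positive
predictivity are both 1.0 up to noise_sd = 0.1 mV).  All detector
internals are configurable (`RunConfig`).

**Beat features.**  With beats at samples r_1 < … < r_B:
RRI_i = (r_{i+1} − r_i)/fs in seconds; RAMP_i is the mean-removed
amplitude at r_i; EDR_i is the rectified area of the mean-removed
signal within ±50 ms of r_i (a QRS-area respiration surrogate — the
respiratory modulation of QRS morphology is what makes ECG-derived
respiration possible).  RAMP and EDR are deliberately kept distinct
(point amplitude vs local area).

**Quality gate.**  A minute is flagged `noise` when its beat count
falls outside [20, 200] or any raw RRI falls outside [0.3, 2.0] s —
physiological-plausibility bounds, configurable.  Noise minutes carry
NaN feature values and are excluded from training and scoring.

**Resampling.**  RRI and RAMP are median-filtered (width 5 beats, for
ectopic suppression) and interpolated with a natural cubic spline onto
a uniform 240-point grid over the minute (one point per 0.25 s); EDR is
spline-interpolated without filtering.  RRI values sit at the midpoint
of their two beats, RAMP/EDR at the beat time.  Outside the first/last
beat the boundary value is held.  The natural boundary condition means
straight-line trends are reproduced exactly; a clear segment needs at
least 4 beats (else it is reclassified as noise).  The result is the
240×3 matrix (columns RRI, RAMP, EDR) the classifiers consume.

**Normalisation.**  Per-column z-scoring with statistics pooled over
the clear matrices of a designated fitting set.  The default scope is
the training split only (no leakage into test statistics);
`normalization_scope` also offers `global` (pooled train+test) and
`per_fold` (refit inside every CV fold).  A zero-variance column maps
to zeros with a logged warning.

## Base classifiers

Three fixed architectures over (240, 3) inputs, all ending in a 2-way
softmax:

* **wang_cnn** — 2 × [conv1d(kernel 3, 64 filters, ReLU) → batch norm →
  maxpool 2] → flatten → dense 100 → dense 10 → softmax.  398,380
  parameters.
* **sharan_cnn** — 3 × [conv1d(kernel 10; 64/128/256 filters, ReLU) →
  maxpool 2] → flatten → dense 64 → dense 256 → softmax.  920,706
  parameters.
* **almutairi_cnn_lstm** — the minute is split into 4 consecutive 60×3
  sub-windows; a shared stack of 3 × [conv1d(kernel 3; 64/128/16,
  ReLU) → batch norm → maxpool 2 → dropout 0.2] encodes each window,
  an LSTM(64) runs over the 4 steps, then dense 64 → softmax.  81,522
  parameters.

Convolutions use "same" padding and dense hidden layers use ReLU
(conventional choices where the architecture descriptions leave them
open).  Training is Adam (step size 0.001) on softmax cross-entropy —
for two one-hot classes identical to binary cross-entropy — with
defaults of 100 epochs and batch size 64; scaled-down experiments in
the tests use 4–8 epochs.  The layer kit is plain float64 numpy with
hand-derived backward passes; every layer's gradient is verified
against central differences in the test suite.  Fixed seeds give
bit-identical runs on a given platform (weight init, shuffling and
dropout all draw from seeded generators).

## Fusion rules

Scores from the `l = 3` base models form per-sample l×k probability
blocks.

1. **Majority voting** (decision level): each classifier votes its
   argmax class; ties (impossible for l=3, k=2) fall back to the sum
   rule.
2. **Sum rule**: CS_i = Σ_j p_ij.
3. **Choquet fuzzy fusion**: per sample, densities g_j = 1 − E_j with
   E_j the base-2 entropy of classifier j's probability vector, so
   confident classifiers weigh more *sample by sample*.  λ solves
   1 + λ = Π(1 + λ·g_j); subsets grow by the Sugeno union rule with
   +λ·g(A)·g(B); class scores are the Choquet integral of the sorted
   scores against the measure increments.  With `normalize_densities`
   (default) the densities are divided by their sum, which forces
   λ = 0 and reduces the integral to an entropy-weighted mean — the
   raw-density path (λ ≠ 0) is retained behind the flag and tested
   equally.  If every classifier is maximally uncertain the uniform
   fallback g_j = 1/l applies.
4. **MLP stacker** (trainable): the k·l = 6 concatenated scores feed a
   16-unit ReLU hidden layer and a k-way softmax, trained with the same
   Adam contract.  Inside the evaluation orchestration the stacker
   keeps an epoch floor of 50: it has only ~200 weights, and the
   handful of Adam steps that suffice for the (much larger) CNNs at
   desk scale would leave it effectively untrained.

Tie-breaks are deterministic everywhere: lowest class index, then
lowest classifier index.

### Numerical notes on the λ-solver

The defining equation is solved as a root of
`Σ log1p(λ·g_j) − log1p(λ)` (same sign and roots as the product form,
but immune to catastrophic cancellation near λ = 0) with Brent's
method; brackets are `(0, hi]` with doubling when Σg < 1 and
`[−1+10^−q, 0)` with a decade search when Σg > 1.  Degenerate cases:
densities summing to 1 within 1e-9 give λ = 0 exactly; at most one
density above 1e-9 leaves the union rule inert (λ = 0 by convention);
a density at 1 within machine precision drives the root to its −1
limit and the nearest representable value is returned.  In every case
the solver verifies g(X) = 1 to 1e-8 by folding all densities.  The
entropy definition uses an explicit minus sign and base-2 logarithm,
fixed by the requirement that the two-class maximum equal 1.

## Evaluation

Five measures with apnea positive: accuracy, precision, recall, F1
(harmonic mean of the previous two) and specificity.  Zero-denominator
ratios are reported as NaN with a logged note — silently reporting 0
would corrupt fold averages.  Protocols: a holdout split; a two-fold
swap (train A / test B, swap, average); and shuffled five-fold CV in
which each fold trains on four parts and tests on the fifth
(unstratified by default; a flag enables stratification).

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not ECG morphology: a fixed Mexican-hat QRS template (~0.1 s wide,
unit peak) placed at beat times; normal minutes draw
RR ~ 60/base_hr + N(0, hrv_sd); apnea minutes additionally multiply RR
by (1 + swing·sin(2πt/T)) with T = 45 s — the cyclical
variation-of-heart-rate phenomenon that accompanies obstructive
episodes; R amplitudes are modulated by (1 + depth·sin(2πt·f_resp/60));
Gaussian noise is added, and with a configurable probability a minute
is replaced by high-amplitude broadband noise while keeping its label
(to exercise the quality gate).  Defaults: 75 bpm, hrv_sd 0.04 s,
swing 0.25, 15 breaths/min, amplitude depth 0.15, noise 0.03 mV.

What the generator does *not* model: P/T waves, baseline wander,
electrode artefacts, ectopic beats, inter-subject variability, or
class imbalance.  Synthetic separability is therefore far higher than
in clinical recordings — passing tests demonstrate that the pipeline's
machinery is correct and that the ensemble rules behave as designed,
not that clinical-grade accuracy would be reached on real data.  The
score-matrix generator fabricates classifier outputs with prescribed
per-classifier accuracy (Dirichlet draws concentrated on the intended
class), which is the controlled harness for the fusion rules.

## Desk-scale problem sizes

The heavier tests use 600 synthetic minutes per class with swing 0.4
and 8 training epochs (end-to-end ensemble property), 20,000 fabricated
score samples (fusion-vs-best-base property), and 2,000 samples for the
stacker recovery check; stochastic assertions are retried once on a
second seed.  These sizes were chosen so the full suite completes in a
few minutes on one CPU while keeping the binomial noise on accuracy
estimates well below the asserted margins.

## Known limitations

* No multi-lead support and no resampling: records must be 100 Hz.
* The WFDB path requires the optional `wfdb` package at runtime.
* Exact bit-reproducibility is promised per platform only; BLAS
  differences across platforms can change low-order bits of training.
* The raw-density Choquet path weighs confident classifiers more even
  when they are confidently wrong; on the fabricated-score harness it
  trails the normalised path, which is why normalisation is the
  default.
* Five-fold CV retrains every base model per fold; at the full
  100-epoch default this is slow on one CPU (use the holdout or
  two-fold protocols for quick experiments).
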