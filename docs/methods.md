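# Methods

This note documents the models and procedures implemented in `eegens`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic validation experiments do and do not demonstrate.

## Signal model of the synthetic cohorts

Each synthetic subject is a channels × samples matrix in µV. Every channel
is an independent sum of six narrowband stochastic oscillations — one per
canonical band (delta 0.5–4 Hz, theta 4–8, alpha 8–12, low-beta 12–20,
high-beta 20–30, gamma 30–45) — plus additive broadband Gaussian noise.
An oscillation is white noise filtered into its band (4th-order
Butterworth, forward-backward) and RMS-normalised; a stochastic process
rather than a pure tone, so different epochs of one subject genuinely
differ and the classification task is non-trivial. Oscillation power is
concentrated in the interior of the band (15% margin off each edge):
adjacent canonical bands share an edge frequency, and physiological
rhythms peak inside their band, so a full-band process would bleed into
the neighbouring band's filtered copy and blur band-restricted analyses.

The per-channel amplitude of band *b* for subject *i* with class label
*y* is

    amplitude = base_b × mult_b(y) × s_i,   s_i ~ LogNormal(0, σ_subject)

* `base_b`: 20/12/15/8/6/5 µV RMS for delta…gamma — a 1/f-flavoured
  profile that keeps clean channels well under the 75 µV QC threshold;
* `mult_b(y)`: the class effect. The default profile gives class 1 a
  1.2× amplitude in delta, alpha and both beta bands, echoing reported
  female-vs-male resting amplitude differences; validation experiments
  override it explicitly;
* `σ_subject = 0.2`: between-subject variability, enough to create subject
  overlap without washing out moderate effects;
* broadband noise SD 5 µV.

Bad channels are injected per channel: flat (constant zero) with
probability `p_flat_channel`, or with an extra 150 µV noise component
(pushing the SD above the 75 µV rule) with probability `p_noisy_channel`.

What the generator does **not** emulate: ocular/muscle artifacts,
mains-line interference, volume conduction and inter-channel correlation,
non-stationarity, or diagnostic heterogeneity. Passing tests on these
cohorts therefore demonstrates that the pipeline's machinery (filtering,
epoching, training, voting, rejection) is correct and that band-specific
amplitude effects are recoverable — not that any particular accuracy level
transfers to real EEG.

Cohort generation is a pure function of the `CohortSpec` (seeds are spawned
per subject from the cohort seed), so identical specs reproduce
bit-identical cohorts.

The cohort directory format is one `.npy` + JSON sidecar per subject
(default) or 16-bit EDF, plus `manifest.csv`. The EDF writer uses 1-s data
records and per-channel physical scaling; round-trips are lossless to the
format's 16-bit quantisation, and files open in independent EDF readers.

## Preprocessing

* **Channel QC**: exclude channels with amplitude SD > 75 µV or exactly
  zero SD, re-checking on the unchanged signals until a pass excludes
  nothing (with a fixed threshold this converges after one productive
  pass; the loop keeps the procedure explicit). Recordings with more than
  30% excluded channels (strict inequality) are rejected.
* **Interpolation**: an excluded channel is replaced by an
  inverse-distance-weighted average of its 6 nearest kept channels on the
  unit-sphere montage — a convex combination, so the replacement lies
  pointwise within the kept channels' envelope. Spherical-spline
  interpolation would be the high-fidelity alternative; IDW preserves the
  contracts that matter here (identity, symmetry, convexity) with far less
  machinery.
* **Filtering**: zero-phase Butterworth band-pass, order 8, applied
  forward-backward (`sosfiltfilt`). Order 8 keeps 60 Hz leakage through a
  1–45 Hz filter below 1% RMS while zero-phase application avoids phase
  distortion at epoch boundaries. Filtering is idempotent in-band: a
  second application changes the 1–45 Hz periodogram-band RMS by < 2%.
* **Epoching**: discard the first 30 s, cut the next `extract_s` seconds
  into consecutive half-open 2-s windows (no overlap, 0-based indices).
  Default extractions are 120 s (train) / 60 s (validation) / 80 s (test);
  training epochs are then thinned to even indices (0, 2, 4, …) because
  successive resting-state epochs are highly correlated.
* The montage is a Fibonacci sphere lattice; only relative distances
  matter for interpolation.

## Classifiers and training

Two compact convolutional families operate on raw epochs
([channels × samples]):

* **inception**: `depth` modules, each concatenating a bottleneck-fed set
  of parallel convolutions (kernel sizes 9/19/39 by default, scaled down
  in desk configurations) with a max-pool + 1×1 branch; a linear-projection
  residual shortcut joins every third module; global average pooling over
  time feeds the output unit. Depth is restricted to {2, 4, 6, 8, 10};
  parameter count is strictly increasing in depth.
* **eegnet**: a temporal convolution shared across channels (F1 filters),
  a depthwise spatial convolution collapsing the channel axis (2 filters
  per temporal map), average-pool ÷4, then a separable temporal
  convolution and average-pool ÷8, flattened into the output unit. ELU
  activations and light (rate 0.25) internal dropout, active only during
  training.

Either family can append the **adapted dropout head** (ADS): dense-32 +
ReLU + dropout (rate 0.5). This dropout layer is the one sampled by Monte
Carlo dropout at inference.

Inputs are divided by a single scalar — the training set's global SD —
recorded with the checkpoint. This brings µV-scale signals to unit order
for the Glorot-initialised first layer while preserving between-epoch
amplitude differences, which are often the class discriminant; per-epoch
standardisation would erase them.

The training protocol: binary cross-entropy, Adam at 0.005, batch size 64
(128 in desk experiments), up to 50 passes over the training set.
Validation loss is evaluated after each pass; the best weights are
checkpointed and returned. Early stopping triggers after 15 consecutive
passes without strict improvement; the learning rate halves after 5 stale
passes (counter resets after each decay). "Iteration" means one pass over
the training set. Loss/optimizer choices (BCE, Adam) and the decay factor
0.5 are conventional defaults, exposed in `TrainingConfig`.

The layer engine is plain numpy with hand-written backward passes
(convolutions as im2col + BLAS matmul, float32 by default) and is verified
against central finite differences in the test suite. With a fixed seed,
build + data order + dropout are all driven by explicit generators, so
training histories are reproducible on a given machine.

## Ensembles, voting, uncertainty

All strategies emit the same object: an M × N matrix of member-by-epoch
class-1 probabilities. Random-weight ensembles draw member seeds from a
seed sequence over the base seed; members differ only in their
initialisation (uniform ±0.05 or normal SD 0.05 — the distributions define
the strategy, the scale is a conventional initialiser default). The
frequency ensemble trains one member per band and ranks them by
per-subject majority-vote accuracy on the validation set (the framework's
headline metric); at prediction time each member receives the test signal
filtered to its own band, with single-store input available for the
literal broadband reading. Ties in the ranking resolve in canonical band
order.

Voting ties (even epoch or member counts) resolve by the relevant mean
probability against the 0.5 threshold, then to class 1 — deterministic and
using all available evidence. A probability of exactly 0.5 classifies as
class 1.

Per-epoch uncertainty is the population variance (÷M) of member
probabilities: the rejection ranking is invariant to the ÷M vs ÷(M−1)
choice, and the population form stays uninflated for 2-member tensors.
Rejection removes ⌊p/100 × n⌋ epochs per subject (never more than the
stated fraction; ties in variance keep the earlier epoch). Per-subject
scope is the default so every subject retains epochs to vote on; pooled
scope is available, and a subject emptied by pooled rejection falls back
to its full-data prediction and is flagged. Error decreases are undefined
at 100% prior accuracy; those cells raise, are recorded as missing, and
are excluded (with a count) from the average/average-max/max summaries.

AUC is rank-based (ties ½), computed on epoch-level ensemble-mean scores
pooled over the test fold by default; a subject-level variant averages
scores within subject first. Fold-level metrics aggregate as mean ±
t-based 95% half-width (t quantile at k−1 df over the k fold values) —
the standard small-k interval.

## Cross-validation and orchestration

Folds are a class-stratified random partition generated once per
experiment; rotation r tests fold r, validates fold r+1 (mod 5), trains on
the rest. A leakage assertion scans every rotation for subject overlap
between roles. The experiment driver derives every stage seed
deterministically from the experiment seed, logs per-stage timings and
writes tidy CSVs; reruns with the same configuration are byte-identical.

The per-band report aggregates band-restricted accuracies three ways —
best single fold, best run mean, mean over all runs — where repeated runs
re-seed model initialisation while the fold assignment stays fixed (the
split is generated once).

## Desk-scale validation experiments

The reference experiments (`eegens.experiments`) fix problem sizes chosen
for a single CPU:

* **Band recovery**: 200 subjects, 8 channels, 100 Hz, 50 s per subject;
  class-1 amplitude ×1.5 in alpha and low-beta only; extractions 20/12/16 s
  (train/validation/test); width-4 depth-2 inception models; full training
  protocol; 5-fold CV. Informative-band models reach ~85% per-subject
  accuracy; the matched zero-effect cohort stays within the 95% binomial
  band around 50% (pooled over all 200 tested subjects).
* **Ensemble run**: 60 subjects under the same cohort conditions, with a
  3-member random-uniform ensemble and a 50-pass Monte Carlo dropout
  ensemble, both voting schemes, and the full rejection grid. At this
  scale the rejection summaries are noisy (fold test sets of 12 subjects);
  they exercise the machinery rather than estimate the real-data benefit
  of rejection, which depends on the error structure of real EEG.

## Known limitations

* Model widths default far below production scale; full-size widths are
  configuration, but CPU training at that scale is slow.
* The numpy engine is single-threaded-deterministic but has no GPU path
  and no batch normalisation; very deep configurations (depth 10) train
  slowly and may need more iterations than the default protocol.
* IDW interpolation underestimates spatial structure compared with
  spherical splines; acceptable for QC-replacement, not for source-level
  work.
* The model-pool strategy reuses members trained earlier in the same
  rotation when available and otherwise trains a default trio
  (inception, eegnet, ADS-inception); it does not persist members across
  rotations.
* Rejection-curve per-epoch accuracy is reported on surviving epochs only
  and is undefined (NaN) when a pooled rejection removes everything.
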