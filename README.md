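# eegens

Uncertainty-aware deep-ensemble classification of multi-channel EEG.

`eegens` implements an end-to-end framework for subject-level binary
classification from resting-state EEG: signal cleaning and epoching, compact
convolutional classifiers (inception-style and EEGNet-style), five
deep-ensemble construction strategies, subject-level majority voting, and a
selective-prediction procedure that discards the epochs on which the
ensemble disagrees most. A synthetic-cohort generator with injectable,
band-specific class effects makes every stage testable without any real
recordings.

It is written for researchers studying ensemble methods and uncertainty
estimation on EEG — the kind of pipeline used, for example, to benchmark
sex classification from high-density paediatric EEG.

## The method

**Data model.** A recording is a channels × samples matrix in µV at a fixed
sampling rate. After channel quality control (exclude channels with
amplitude SD > 75 µV or no variation; reject a recording if > 30% of its
channels fail; interpolate excluded channels from their neighbours) and a
zero-phase 1–45 Hz band-pass, the first 30 s are discarded and the signal is
cut into non-overlapping 2-s epochs — 120 s for training (thinned to every
other epoch), 60 s for validation, 80 s (40 epochs) for testing. Subjects
are split once into five class-stratified folds; each of the five rotations
trains on three folds, validates on one, tests on the last, so every
subject is tested exactly once.

**Classifiers.** An epoch classifier maps one epoch to P(class 1). Training
uses Adam (initial learning rate 0.005, halved after 5 stale iterations),
up to 50 iterations with early stopping at patience 15, returning the
checkpoint with minimum validation loss.

**Ensembles.** Five ways to obtain member predictions
p<sub>m</sub>(epoch): random-initialisation ensembles (uniform or normal
initialiser, 5 members), a depth ensemble (inception depths 2, 4, 6, 8,
10), Monte Carlo dropout through an adapted head (dense-32 + dropout 0.5;
50 stochastic forward passes as implicit members), a pool of previously
trained heterogeneous models, and a frequency ensemble (one member per
canonical band — delta 0.5–4, theta 4–8, alpha 8–12, low-beta 12–20,
high-beta 20–30, gamma 30–45 Hz — keeping the top 3 by validation
accuracy).

**Voting.** Per subject, either each member votes by within-subject
majority and the member verdicts are majority-combined (*ensemble
subject*), or member probabilities are averaged per epoch before the
within-subject majority (*ensemble epoch*). Ties resolve by mean
probability against 0.5, then to class 1.

**Uncertainty.** For each epoch, the population variance of the member
probabilities, Var(p₁…p_M), scores disagreement. The p% most uncertain
epochs (per subject) are discarded and the vote re-run; performance changes
are summarised as the relative error decrease
(err_before − err_after)/err_before × 100 over p ∈ {10, 25, 50, 75, 90}.

## Worked example

```python
from eegens import (CohortSpec, generate_cohort, preprocess_recording,
                    segment_epochs, thin_training_epochs, EpochDataset,
                    EpochClassifier, ModelSpec, TrainingConfig)

# 20 subjects whose class-1 members have 1.8x alpha amplitude
spec = CohortSpec(n_subjects=20, n_channels=6, sampling_rate=100.0,
                  duration=50.0, band_effects={"alpha": (1.0, 1.8)}, seed=7)
cohort = [preprocess_recording(r) for r in generate_cohort(spec)]

def store(recs, role, seconds):
    arrays = [segment_epochs(r, seconds, role) for r in recs]
    if role == "train":
        arrays = [thin_training_epochs(a) for a in arrays]
    return EpochDataset.from_epoch_arrays(arrays)

train = store(cohort[:12], "train", 16.0)
val = store(cohort[12:16], "validation", 8.0)
test = store(cohort[16:], "test", 8.0)

clf = EpochClassifier(ModelSpec(width=4, depth=2, kernel_sizes=(3, 7, 15)))
result = clf.fit(train, val, TrainingConfig(max_iterations=20, batch_size=32))
print(result.summary())
```

prints

```
inception classifier (depth=2, width=4, ads=False, init=glorot_uniform, band=broadband)
  parameters:     1033
  iterations run: 20
  best val loss:  0.5069
```

i.e. a 1033-parameter depth-2 inception classifier trained for all 20
iterations, reaching a validation cross-entropy of about 0.51 (well below
the 0.69 of a chance-level predictor at this tiny scale — the alpha
amplitude effect is being learned). `result.predict_proba(test)` then gives
one class-1 probability per test epoch, and `eegens.evaluate` /
`eegens.uncertainty` turn those into subject-level votes and
rejection curves.

A full experiment — simulate, preprocess, 5-fold cross-validation, several
ensembles, voting and rejection — runs from one YAML file:

```bash
eegens run --config experiment.yaml --out results/
eegens report --results results/
```

and writes tidy CSVs (`evaluation.csv`, `cv_summary.csv`,
`rejection_curve.csv`, `table3_summary.csv`) plus a seeded run manifest.

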