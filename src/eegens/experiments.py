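"""Canned desk-scale reference experiments.

These fix the study conditions for the package's own validation runs so
that the test suite and the acceptance script execute the identical
protocol.  The scales are chosen for a single CPU: 200 subjects, 8
channels at 100 Hz, compact models (width 4, depth 2), with the full
training protocol (50 iterations, early stopping, LR schedule).
"""

from __future__ import annotations

import pandas as pd

from .ensembles import EnsembleSpec
from .models import ModelSpec, TrainingConfig
from .pipeline import ExperimentConfig, run_band_experiment
from .synthdata import CohortSpec

__all__ = [
    "DESK_MODEL",
    "DESK_TRAINING",
    "band_recovery_config",
    "run_band_recovery",
    "desk_ensemble_config",
]

#: Compact classifier used by the desk-scale experiments.
DESK_MODEL = ModelSpec(width=4, depth=2, kernel_sizes=(3, 7, 15))

#: Full training protocol at a desk-scale batch size.
DESK_TRAINING = TrainingConfig(max_iterations=50, batch_size=128)

#: Class-1 amplitude multiplier injected into the informative bands.
EFFECT_MULTIPLIER = 1.5
INFORMATIVE_BANDS = ("alpha", "low_beta")


def band_recovery_config(seed: int, *, effect: bool = True,
                         n_subjects: int = 200) -> ExperimentConfig:
    """Cohort + protocol for the band-recovery experiment.

    The cohort carries a class-1 amplitude effect only in the alpha and
    low-beta bands (or no effect at all for the null condition); models are
    then trained band-restricted, so informative bands should recover the
    effect while the null condition must stay at chance.
    """
    mult = EFFECT_MULTIPLIER if effect else 1.0
    cohort = CohortSpec(
        n_subjects=n_subjects,
        n_channels=8,
        sampling_rate=100.0,
        duration=50.0,
        band_effects={band: (1.0, mult) for band in INFORMATIVE_BANDS},
        seed=seed,
    )
    return ExperimentConfig(
        cohort=cohort,
        extract_seconds={"train": 20.0, "validation": 12.0, "test": 16.0},
        base_model=DESK_MODEL,
        training=DESK_TRAINING,
        n_repeat_runs=1,
        seed=seed,
    )


def run_band_recovery(seed: int, *, effect: bool = True,
                      bands=INFORMATIVE_BANDS, n_folds: int = 5) -> pd.DataFrame:
    """Train band-restricted models across folds; tidy accuracy frame."""
    config = band_recovery_config(seed, effect=effect)
    return run_band_experiment(config, bands=list(bands),
                               n_folds_per_run=n_folds)


def desk_ensemble_config(seed: int, n_subjects: int = 60) -> ExperimentConfig:
    """A small multi-ensemble experiment exercising voting and rejection."""
    cohort = CohortSpec(
        n_subjects=n_subjects,
        n_channels=8,
        sampling_rate=100.0,
        duration=50.0,
        band_effects={band: (1.0, EFFECT_MULTIPLIER)
                      for band in INFORMATIVE_BANDS},
        seed=seed,
    )
    ads_base = ModelSpec(width=4, depth=2, kernel_sizes=(3, 7, 15),
                         ads=True, dropout_rate=0.5)
    return ExperimentConfig(
        cohort=cohort,
        extract_seconds={"train": 20.0, "validation": 12.0, "test": 16.0},
        base_model=DESK_MODEL,
        training=DESK_TRAINING,
        ensembles=(
            EnsembleSpec(strategy="weights_uniform", n_members=3, base=DESK_MODEL),
            EnsembleSpec(strategy="ads_mcd", n_forward=50, base=ads_base),
        ),
        seed=seed,
    )
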