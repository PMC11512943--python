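"""Variance-based uncertain-epoch rejection (selective prediction).

Ensemble disagreement quantifies epistemic uncertainty: for each epoch the
population variance of the member probabilities is the uncertainty score.
The most uncertain fraction p of epochs is discarded and the voting scheme
re-run on the survivors; sweeping p over {0, 10, 25, 50, 75, 90}% traces a
rejection curve.  Improvements are reported as the percentage decrease of
the error rate, aggregated as average / average-maximum / maximum over
ensembles and folds.

Rejection operates per subject by default (each subject loses its own top
p% epochs, so every subject retains epochs to vote on); ``pooled=True``
ranks epochs across the whole test set instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluate import SCHEMES, ensemble_epoch_vote, ensemble_subject_vote
from .ensembles import PredictionTensor
from .synthdata import ConfigurationError

__all__ = [
    "UncertaintyScores",
    "epoch_variance",
    "reject_uncertain",
    "rejection_curve",
    "error_decrease",
    "summarize_table3",
    "DEFAULT_P_GRID",
]

DEFAULT_P_GRID = (0, 10, 25, 50, 75, 90)


@dataclass
class UncertaintyScores:
    """Per-epoch population variance of member probabilities."""

    variance: np.ndarray       # [n_epochs], in [0, 0.25] for probabilities
    epoch_to_subject: np.ndarray

    def __post_init__(self) -> None:
        self.variance = np.asarray(self.variance, dtype=float)


def epoch_variance(tensor: PredictionTensor) -> UncertaintyScores:
    """Population variance (÷n) of member probabilities, per epoch.

    The ranking used for rejection is invariant to the ÷n vs ÷(n−1)
    choice; the population form stays finite and uninflated for 2-member
    tensors.
    """
    if tensor.n_members < 2:
        raise ConfigurationError("uncertainty needs at least 2 ensemble members")
    return UncertaintyScores(
        variance=tensor.probs.var(axis=0, ddof=0),
        epoch_to_subject=tensor.epoch_to_subject,
    )


def _reject_from_scores(variance: np.ndarray, p: float) -> np.ndarray:
    """Kept indices after removing the floor(p% · n) highest-variance epochs.

    Ties in variance break by epoch index: among equal scores the earlier
    epoch is kept.
    """
    n = variance.size
    n_remove = int(np.floor(p / 100.0 * n))
    if n_remove == 0:
        return np.arange(n)
    # sort by (-variance, -index): highest variance first, later index first
    order = np.lexsort((-np.arange(n), -variance))
    removed = order[:n_remove]
    keep = np.setdiff1d(np.arange(n), removed)
    return keep


def reject_uncertain(tensor: PredictionTensor, scores: UncertaintyScores,
                     p: float, pooled: bool = False) -> np.ndarray:
    """Sorted epoch indices surviving removal of the top-p% most uncertain.

    Per-subject by default: each subject's own top p% is removed, so the
    kept sets are nested in p within every subject.
    """
    if not 0 <= p < 100:
        raise ConfigurationError("p must lie in [0, 100)")
    if pooled:
        return _reject_from_scores(scores.variance, p)
    sids = np.asarray(scores.epoch_to_subject, dtype=object)
    kept: list[np.ndarray] = []
    for s in dict.fromkeys(sids):
        idx = np.flatnonzero(sids == s)
        kept.append(idx[_reject_from_scores(scores.variance[idx], p)])
    return np.sort(np.concatenate(kept))


def error_decrease(acc_before: float, acc_after: float) -> float:
    """Relative reduction of the error rate, in percent.

    Undefined when the error before rejection is zero; raises so callers
    exclude (and flag) those cells rather than silently averaging them.
    """
    if not (0 <= acc_before <= 100 and 0 <= acc_after <= 100):
        raise ValueError("accuracies must be percentages in [0, 100]")
    err_before = 100.0 - acc_before
    if err_before == 0.0:
        raise ZeroDivisionError("error decrease undefined at 100% accuracy")
    return (err_before - (100.0 - acc_after)) / err_before * 100.0


def rejection_curve(tensor: PredictionTensor,
                    subject_labels: Mapping[str, int],
                    scheme: str = "ensemble_epoch",
                    p_grid: Sequence[float] = DEFAULT_P_GRID,
                    pooled: bool = False) -> pd.DataFrame:
    """Re-evaluate the voting scheme after each rejection level.

    Returns one row per p with per-subject accuracy, per-epoch accuracy
    (ensemble-mean predictions on surviving epochs) and the number of kept
    epochs.  A subject whose epochs are all removed keeps its p = 0
    prediction and is flagged in ``n_fallback_subjects``.
    """
    if len(p_grid) == 0:
        raise ConfigurationError("p_grid must be non-empty")
    if scheme not in SCHEMES:
        raise ConfigurationError(f"unknown scheme {scheme!r}")
    vote = ensemble_subject_vote if scheme == "ensemble_subject" else ensemble_epoch_vote
    scores = epoch_variance(tensor)
    sids = np.asarray(tensor.epoch_to_subject, dtype=object)
    subjects = tensor.subjects
    mean = tensor.mean_probs()
    epoch_labels = np.array([subject_labels[str(s)] for s in sids])
    full_pred = {s: vote(tensor, s) for s in subjects}

    rows = []
    for p in p_grid:
        keep = reject_uncertain(tensor, scores, p, pooled=pooled)
        kept_mask = np.zeros(tensor.n_epochs, dtype=bool)
        kept_mask[keep] = True
        sub_tensor = PredictionTensor(
            probs=tensor.probs[:, keep],
            epoch_to_subject=sids[keep],
            member_ids=tensor.member_ids,
        )
        correct = 0
        fallback = 0
        for s in subjects:
            if kept_mask[sids == s].any():
                pred = vote(sub_tensor, s)
            else:
                pred = full_pred[s]
                fallback += 1
            correct += int(pred == subject_labels[s])
        pe = float(np.mean((mean[keep] >= 0.5).astype(int) == epoch_labels[keep]) * 100.0) \
            if keep.size else float("nan")
        rows.append({
            "p_removed": p,
            "per_subject_accuracy": 100.0 * correct / len(subjects),
            "per_epoch_accuracy": pe,
            "n_epochs_kept": int(keep.size),
            "n_fallback_subjects": fallback,
            "scheme": scheme,
            "pooled": pooled,
        })
    return pd.DataFrame(rows)


def summarize_table3(decreases: pd.DataFrame) -> pd.DataFrame:
    """Aggregate error decreases over (ensemble, fold) per rejection level.

    Input columns: ``ensemble``, ``fold``, ``p_removed``, ``decrease``
    (NaN cells — undefined decreases — are excluded).  Output: one row per
    p with ``avg`` (mean over all cells), ``avg_max`` (mean over ensembles
    of each ensemble's best fold) and ``max`` (global best), plus the
    corresponding percentage of kept epochs.
    """
    if decreases.empty:
        raise ValueError("no error decreases to summarise")
    d = decreases.dropna(subset=["decrease"])
    rows = []
    for p, grp in d.groupby("p_removed", sort=True):
        per_ens_max = grp.groupby("ensemble")["decrease"].max()
        rows.append({
            "p_removed": p,
            "pct_kept_epochs": 100 - p,
            "avg_error_decrease": float(grp["decrease"].mean()),
            "avg_max_error_decrease": float(per_ens_max.mean()),
            "max_error_decrease": float(grp["decrease"].max()),
            "n_cells": int(len(grp)),
        })
    return pd.DataFrame(rows)
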