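"""Cross-validation scheme, voting rules and performance metrics.

Subjects are split once into five class-stratified folds; each of the five
rotations trains on three folds, validates on one and tests on the
remaining one, so every subject is tested exactly once.

Three granularities of accuracy are reported:

* per-epoch — every 2-s epoch scored as an independent prediction;
* per-subject — majority vote over a subject's epoch predictions;
* ensemble votes — either each member votes per subject and the member
  verdicts are majority-combined ("ensemble subject"), or member
  probabilities are averaged per epoch before the within-subject majority
  ("ensemble epoch").

Ties at any stage resolve by the relevant mean probability against 0.5,
then to class 1.  AUC is the rank-based probability that a random positive
outranks a random negative, computed on pooled epoch-level scores by
default.  Fold-level results aggregate to mean ± a Student-t 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "FoldSplit",
    "EvalResult",
    "make_folds",
    "rotations",
    "per_epoch_accuracy",
    "subject_majority",
    "subject_accuracy_from_probs",
    "ensemble_subject_vote",
    "ensemble_epoch_vote",
    "auc",
    "evaluate_tensor",
    "summarize_cv",
    "SCHEMES",
]

SCHEMES = ("single", "ensemble_subject", "ensemble_epoch")
THRESHOLD = 0.5


@dataclass(frozen=True)
class FoldSplit:
    n_folds: int
    assignment: dict[str, int]          # subject_id -> fold index
    seed: int

    def fold_subjects(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f == fold]


def make_folds(subject_labels: Mapping[str, int], n_folds: int = 5,
               seed: int = 0) -> FoldSplit:
    """Class-stratified random partition of subjects into folds.

    Generated once per experiment and reused by every rotation; per-fold
    class counts differ by at most one within each class.
    """
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for cls in (0, 1):
        ids = sorted(s for s, lab in subject_labels.items() if lab == cls)
        if len(ids) < n_folds:
            raise ValueError(
                f"class {cls} has {len(ids)} subjects; need at least {n_folds}"
            )
        ids = [ids[i] for i in rng.permutation(len(ids))]
        for i, s in enumerate(ids):
            assignment[s] = i % n_folds
    return FoldSplit(n_folds=n_folds, assignment=assignment, seed=seed)


def rotations(split: FoldSplit) -> list[dict[str, list[str]]]:
    """The k train/validation/test role maps; rotation r tests fold r."""
    out = []
    for r in range(split.n_folds):
        val = (r + 1) % split.n_folds
        train_folds = [f for f in range(split.n_folds) if f not in (r, val)]
        out.append({
            "train": [s for f in train_folds for s in split.fold_subjects(f)],
            "validation": split.fold_subjects(val),
            "test": split.fold_subjects(r),
        })
    return out


def per_epoch_accuracy(probs: np.ndarray, labels: np.ndarray,
                       threshold: float = THRESHOLD) -> float:
    """Percentage of epochs classified correctly (prob >= 0.5 -> class 1)."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if probs.size == 0:
        raise ValueError("no epochs to score")
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must have equal length")
    pred = (probs >= threshold).astype(int)
    return float(np.mean(pred == labels) * 100.0)


def subject_majority(probs: np.ndarray, threshold: float = THRESHOLD) -> int:
    """Majority class over one subject's epoch predictions.

    An even split resolves by the subject's mean probability against the
    threshold; a mean exactly at the threshold resolves to class 1.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        raise ValueError("subject has no epochs")
    votes = (probs >= threshold).astype(int)
    ones = int(votes.sum())
    zeros = votes.size - ones
    if ones > zeros:
        return 1
    if zeros > ones:
        return 0
    return 1 if probs.mean() >= threshold else 0


def subject_accuracy_from_probs(probs: np.ndarray, subject_ids: Sequence,
                                subject_labels: Mapping[str, int],
                                threshold: float = THRESHOLD) -> float:
    """Per-subject majority-vote accuracy (%) from epoch-level scores."""
    probs = np.asarray(probs, dtype=float)
    sids = np.asarray(subject_ids, dtype=object)
    correct = 0
    subjects = list(dict.fromkeys(str(s) for s in sids))
    for s in subjects:
        pred = subject_majority(probs[sids == s], threshold)
        correct += int(pred == subject_labels[s])
    return 100.0 * correct / len(subjects)


def ensemble_subject_vote(tensor, subject: str,
                          threshold: float = THRESHOLD) -> int:
    """Each member votes per subject; the member verdicts are combined.

    A tie across members resolves by the ensemble-mean probability over the
    subject's epochs (then class 1 at exactly the threshold).
    """
    idx = tensor.epochs_of(subject)
    if idx.size == 0:
        raise ValueError(f"subject {subject!r} has no epochs in the tensor")
    verdicts = [subject_majority(tensor.probs[m, idx], threshold)
                for m in range(tensor.n_members)]
    ones = sum(verdicts)
    zeros = len(verdicts) - ones
    if ones > zeros:
        return 1
    if zeros > ones:
        return 0
    return 1 if tensor.probs[:, idx].mean() >= threshold else 0


def ensemble_epoch_vote(tensor, subject: str,
                        threshold: float = THRESHOLD) -> int:
    """Average member probabilities per epoch, then within-subject majority."""
    idx = tensor.epochs_of(subject)
    if idx.size == 0:
        raise ValueError(f"subject {subject!r} has no epochs in the tensor")
    return subject_majority(tensor.probs[:, idx].mean(axis=0), threshold)


def auc(probs: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(random positive outranks random negative), ties ½."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(probs, dtype=float)))


@dataclass
class EvalResult:
    per_epoch_accuracy: float
    per_subject_accuracy: float
    auc: float
    scheme: str
    fold: int = 0
    ensemble: str = ""


def evaluate_tensor(tensor, subject_labels: Mapping[str, int],
                    scheme: str = "ensemble_epoch", fold: int = 0,
                    ensemble: str = "", subject_level_auc: bool = False) -> EvalResult:
    """Score a prediction tensor under one voting scheme.

    Per-epoch accuracy and AUC always use the per-epoch ensemble-mean
    probabilities (pooled over the fold's test epochs); the per-subject
    accuracy uses the requested vote.  ``subject_level_auc`` switches the
    AUC to per-subject mean scores.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    mean = tensor.mean_probs()
    sids = np.asarray(tensor.epoch_to_subject, dtype=object)
    epoch_labels = np.array([subject_labels[str(s)] for s in sids])

    vote = {"single": ensemble_epoch_vote,     # degenerate: 1-member tensor
            "ensemble_subject": ensemble_subject_vote,
            "ensemble_epoch": ensemble_epoch_vote}[scheme]
    subjects = tensor.subjects
    correct = sum(int(vote(tensor, s) == subject_labels[s]) for s in subjects)
    if subject_level_auc:
        subj_scores = np.array([mean[sids == s].mean() for s in subjects])
        subj_labels = np.array([subject_labels[s] for s in subjects])
        auc_val = auc(subj_scores, subj_labels)
    else:
        auc_val = auc(mean, epoch_labels)
    return EvalResult(
        per_epoch_accuracy=per_epoch_accuracy(mean, epoch_labels),
        per_subject_accuracy=100.0 * correct / len(subjects),
        auc=auc_val,
        scheme=scheme,
        fold=fold,
        ensemble=ensemble,
    )


def summarize_cv(results: Iterable[EvalResult]) -> pd.DataFrame:
    """Fold-level mean ± t-based 95% CI half-width per metric.

    One row per (ensemble, scheme, metric); the half-width is
    t(0.975, k−1) · sd/√k over the k fold values.
    """
    rows = [r.__dict__ for r in results]
    if len(rows) < 2:
        raise ValueError("need results from at least 2 folds")
    df = pd.DataFrame(rows)
    out = []
    for (ens, scheme), grp in df.groupby(["ensemble", "scheme"], sort=False):
        for metric in ("per_epoch_accuracy", "per_subject_accuracy", "auc"):
            vals = grp[metric].to_numpy(dtype=float)
            k = len(vals)
            if k < 2:
                raise ValueError("need at least 2 folds per group")
            half = float(stats.t.ppf(0.975, k - 1) * vals.std(ddof=1) / np.sqrt(k))
            out.append({"ensemble": ens, "scheme": scheme, "metric": metric,
                        "mean": float(vals.mean()), "ci95_halfwidth": half,
                        "n_folds": k})
    return pd.DataFrame(out)
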