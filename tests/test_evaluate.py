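"""Fold construction, voting rules, AUC and CV summaries against oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegens.ensembles import PredictionTensor
from eegens.evaluate import (
    auc,
    ensemble_epoch_vote,
    ensemble_subject_vote,
    evaluate_tensor,
    make_folds,
    per_epoch_accuracy,
    rotations,
    subject_majority,
    summarize_cv,
    EvalResult,
)


# -- independent voting oracles (pure python, straight from the rules) -------

def oracle_majority(ps):
    votes = [1 if p >= 0.5 else 0 for p in ps]
    ones, zeros = sum(votes), len(votes) - sum(votes)
    if ones != zeros:
        return 1 if ones > zeros else 0
    return 1 if sum(ps) / len(ps) >= 0.5 else 0


def oracle_subject_vote(rows):
    verdicts = [oracle_majority(r) for r in rows]
    ones, zeros = sum(verdicts), len(verdicts) - sum(verdicts)
    if ones != zeros:
        return 1 if ones > zeros else 0
    flat = [p for r in rows for p in r]
    return 1 if sum(flat) / len(flat) >= 0.5 else 0


def oracle_epoch_vote(rows):
    means = [sum(col) / len(col) for col in zip(*rows)]
    return oracle_majority(means)


def tensor_of(rows, subject="s"):
    rows = np.asarray(rows, dtype=float)
    return PredictionTensor(
        probs=rows,
        epoch_to_subject=np.full(rows.shape[1], subject, dtype=object),
        member_ids=[f"m{i}" for i in range(rows.shape[0])],
    )


class TestFolds:
    def test_balanced_1780_roster_gives_356_per_fold(self):
        labels = {f"S{i:04d}": i % 2 for i in range(1780)}
        split = make_folds(labels, n_folds=5, seed=0)
        for f in range(5):
            fold = split.fold_subjects(f)
            assert len(fold) == 356
            assert sum(labels[s] for s in fold) == 178

    def test_ten_subjects_five_folds(self):
        labels = {f"S{i}": i % 2 for i in range(10)}
        split = make_folds(labels, n_folds=5, seed=1)
        for f in range(5):
            fold = split.fold_subjects(f)
            assert len(fold) == 2
            assert sum(labels[s] for s in fold) == 1

    def test_deterministic_for_seed(self):
        labels = {f"S{i}": i % 2 for i in range(40)}
        a = make_folds(labels, seed=7)
        b = make_folds(labels, seed=7)
        assert a.assignment == b.assignment
        c = make_folds(labels, seed=8)
        assert c.assignment != a.assignment

    def test_class_too_small_rejected(self):
        labels = {"a": 0, "b": 0, "c": 0, "d": 0, "e": 0, "f": 1}
        with pytest.raises(ValueError, match="class 1"):
            make_folds(labels, n_folds=5)

    @pytest.mark.parametrize("n,seed", [(15, 0), (23, 3), (100, 9)])
    def test_rotations_cover_every_subject_once(self, n, seed):
        labels = {f"S{i}": i % 2 for i in range(n)}
        split = make_folds(labels, seed=seed)
        maps = rotations(split)
        assert len(maps) == 5
        tested = []
        for r, roles in enumerate(maps):
            assert set(roles["test"]) == set(split.fold_subjects(r))
            assert not (set(roles["train"]) & set(roles["validation"]))
            assert not (set(roles["train"]) & set(roles["test"]))
            assert not (set(roles["validation"]) & set(roles["test"]))
            assert len(roles["train"]) + len(roles["validation"]) \
                + len(roles["test"]) == n
            tested += roles["test"]
        assert sorted(tested) == sorted(labels)


class TestPerEpochAccuracy:
    def test_examples(self):
        assert per_epoch_accuracy([0.9, 0.1], [1, 0]) == 100.0
        assert per_epoch_accuracy([0.9, 0.9], [1, 0]) == 50.0
        assert per_epoch_accuracy([0.5], [1]) == 100.0   # 0.5 -> class 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            per_epoch_accuracy([], [])


class TestSubjectMajority:
    def test_examples(self):
        probs = np.r_[np.full(25, 0.9), np.full(15, 0.1)]
        assert subject_majority(probs) == 1
        tie = np.r_[np.full(20, 0.9), np.full(20, 0.26)]   # mean 0.58
        assert subject_majority(tie) == 1
        assert subject_majority(np.array([0.3])) == 0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    def test_matches_oracle(self, ps):
        assert subject_majority(np.array(ps)) == oracle_majority(ps)


class TestEnsembleVotes:
    def test_worked_examples(self):
        t = tensor_of([[0.9], [0.8], [0.2]])
        assert ensemble_subject_vote(t, "s") == 1       # votes {1,1,0}
        t2 = tensor_of([[0.9, 0.1], [0.2, 0.3]])        # votes {1,0}, mean 0.375
        assert ensemble_subject_vote(t2, "s") == 0
        t3 = tensor_of([[0.9, 0.8], [0.8, 0.9], [0.7, 1.0]])
        assert ensemble_epoch_vote(t3, "s") == 1

    def test_exhaustive_truth_tables(self):
        """All member-vote patterns for <=3 members x <=5 epochs must match
        the brute-force voting oracles, tie rules included."""
        values = (0.2, 0.8)
        for m, e in [(1, 1), (1, 4), (2, 2), (2, 4), (3, 3), (3, 5)]:
            for pattern in itertools.product(values, repeat=m * e):
                rows = np.array(pattern).reshape(m, e)
                t = tensor_of(rows)
                assert ensemble_subject_vote(t, "s") == oracle_subject_vote(rows)
                assert ensemble_epoch_vote(t, "s") == oracle_epoch_vote(rows)

    def test_tie_cases_with_asymmetric_values(self):
        values = (0.1, 0.6)     # votes {0,1} but asymmetric means
        for m, e in [(2, 2), (2, 4), (3, 4)]:
            for pattern in itertools.product(values, repeat=m * e):
                rows = np.array(pattern).reshape(m, e)
                t = tensor_of(rows)
                assert ensemble_subject_vote(t, "s") == oracle_subject_vote(rows)
                assert ensemble_epoch_vote(t, "s") == oracle_epoch_vote(rows)

    def test_identical_members_reduce_to_subject_majority(self):
        rng = np.random.default_rng(0)
        row = rng.random(9)
        t = tensor_of(np.tile(row, (4, 1)))
        expect = subject_majority(row)
        assert ensemble_subject_vote(t, "s") == expect
        assert ensemble_epoch_vote(t, "s") == expect


class TestAUC:
    def test_worked_example_matches_pair_counting(self):
        got = auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        # pairs: (.35,.1)+, (.35,.4)-, (.8,.1)+, (.8,.4)+  -> 3/4
        assert got == pytest.approx(0.75)

    def test_perfect_and_chance(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        assert abs(auc(scores, labels) - 0.5) < 0.03

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(2, 50), st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_pair_counting(self, n, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(n), 2)     # force ties to occur
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auc(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        squashed = 1 / (1 + np.exp(-7 * (scores - 0.4)))
        assert auc(scores, labels) == pytest.approx(auc(squashed, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])


class TestEvaluateTensor:
    def make_tensor(self):
        rng = np.random.default_rng(3)
        sids = np.repeat([f"s{i}" for i in range(6)], 8).astype(object)
        labels = {f"s{i}": i % 2 for i in range(6)}
        probs = np.clip(rng.normal(0.5, 0.2, (3, 48))
                        + 0.25 * np.array([labels[s] * 2 - 1 for s in sids]), 0, 1)
        return PredictionTensor(probs=probs, epoch_to_subject=sids,
                                member_ids=["a", "b", "c"]), labels

    def test_subject_accuracy_100_when_all_epochs_correct(self):
        sids = np.repeat(["x", "y"], 4).astype(object)
        labels = {"x": 1, "y": 0}
        probs = np.vstack([[0.9] * 4 + [0.1] * 4] * 2)
        t = PredictionTensor(probs=probs, epoch_to_subject=sids,
                             member_ids=["a", "b"])
        res = evaluate_tensor(t, labels)
        assert res.per_epoch_accuracy == 100.0
        assert res.per_subject_accuracy == 100.0

    def test_schemes_agree_for_identical_members(self):
        t, labels = self.make_tensor()
        t.probs = np.tile(t.probs[:1], (3, 1))
        a = evaluate_tensor(t, labels, scheme="ensemble_subject")
        b = evaluate_tensor(t, labels, scheme="ensemble_epoch")
        assert a.per_subject_accuracy == b.per_subject_accuracy

    def test_subject_level_auc_option(self):
        t, labels = self.make_tensor()
        res = evaluate_tensor(t, labels, subject_level_auc=True)
        assert 0.0 <= res.auc <= 1.0


class TestCvSummary:
    def make(self, values):
        return [EvalResult(per_epoch_accuracy=v, per_subject_accuracy=v,
                           auc=v / 100, scheme="ensemble_epoch", fold=i,
                           ensemble="e")
                for i, v in enumerate(values)]

    def test_identical_folds_zero_halfwidth(self):
        df = summarize_cv(self.make([90, 90, 90, 90, 90]))
        assert (df["ci95_halfwidth"] == 0).all()
        assert (df.loc[df.metric == "per_subject_accuracy", "mean"] == 90).all()

    def test_worked_t_interval(self):
        from scipy import stats

        df = summarize_cv(self.make([88, 90, 92, 90, 90]))
        row = df[df.metric == "per_subject_accuracy"].iloc[0]
        expect = stats.t.ppf(0.975, 4) * np.std([88, 90, 92, 90, 90], ddof=1) / np.sqrt(5)
        assert row["mean"] == pytest.approx(90.0)
        assert row["ci95_halfwidth"] == pytest.approx(expect)

    def test_order_invariance(self):
        a = summarize_cv(self.make([88, 90, 92, 90, 90]))
        b = summarize_cv(self.make([90, 92, 90, 90, 88]))
        assert a["mean"].tolist() == b["mean"].tolist()

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            summarize_cv(self.make([90]))
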