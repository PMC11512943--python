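"""Variance scores, epoch rejection, rejection curves and error decreases."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegens.ensembles import PredictionTensor
from eegens.synthdata import ConfigurationError
from eegens.uncertainty import (
    DEFAULT_P_GRID,
    epoch_variance,
    error_decrease,
    reject_uncertain,
    rejection_curve,
    summarize_table3,
)


def tensor_of(rows, sids=None):
    rows = np.asarray(rows, dtype=float)
    if sids is None:
        sids = np.full(rows.shape[1], "s", dtype=object)
    return PredictionTensor(probs=rows, epoch_to_subject=np.asarray(sids, dtype=object),
                            member_ids=[f"m{i}" for i in range(rows.shape[0])])


def brute_force_variance(rows):
    """Mean of squared deviations, via explicit python loops."""
    m, n = len(rows), len(rows[0])
    out = []
    for j in range(n):
        mean = sum(rows[i][j] for i in range(m)) / m
        out.append(sum((rows[i][j] - mean) ** 2 for i in range(m)) / m)
    return out


class TestEpochVariance:
    def test_closed_forms(self):
        assert epoch_variance(tensor_of([[0.7], [0.7], [0.7]])).variance[0] \
            == pytest.approx(0.0, abs=1e-30)
        assert epoch_variance(tensor_of([[0.0], [1.0]])).variance[0] == 0.25

    def test_ordering(self):
        t = tensor_of([[0.5, 0.1], [0.5, 0.5], [0.5, 0.9]])
        v = epoch_variance(t).variance
        assert v[1] > v[0]

    def test_matches_brute_force_on_random_tensors(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            m = int(rng.integers(2, 7))
            n = int(rng.integers(1, 9))
            rows = rng.random((m, n))
            v = epoch_variance(tensor_of(rows)).variance
            np.testing.assert_allclose(v, brute_force_variance(rows), atol=1e-12)

    def test_bounded_by_quarter(self):
        rng = np.random.default_rng(1)
        v = epoch_variance(tensor_of(rng.random((6, 50)))).variance
        assert np.all((v >= 0) & (v <= 0.25))

    def test_single_member_rejected(self):
        with pytest.raises(ConfigurationError):
            epoch_variance(tensor_of([[0.5, 0.5]]))


class TestRejection:
    def test_floor_counts_at_40_epochs(self):
        rng = np.random.default_rng(2)
        t = tensor_of(rng.random((3, 40)))
        s = epoch_variance(t)
        assert reject_uncertain(t, s, 10).size == 36
        assert reject_uncertain(t, s, 25).size == 30
        assert reject_uncertain(t, s, 0).size == 40

    def test_nesting_over_grid(self):
        rng = np.random.default_rng(3)
        sids = np.repeat(["a", "b", "c"], 10).astype(object)
        t = tensor_of(rng.random((4, 30)), sids)
        s = epoch_variance(t)
        kept = {p: set(reject_uncertain(t, s, p)) for p in (0, 10, 25, 50, 75, 90)}
        grid = sorted(kept)
        for p1, p2 in zip(grid, grid[1:]):
            assert kept[p2] <= kept[p1]

    def test_variance_ties_keep_earlier_epochs(self):
        t = tensor_of(np.tile([[0.2], [0.8]], (1, 10)))   # all variances equal
        s = epoch_variance(t)
        kept = reject_uncertain(t, s, 30)
        np.testing.assert_array_equal(kept, np.arange(7))

    def test_member_permutation_invariance(self):
        rng = np.random.default_rng(4)
        rows = rng.random((5, 20))
        t1, t2 = tensor_of(rows), tensor_of(rows[::-1])
        s1, s2 = epoch_variance(t1), epoch_variance(t2)
        np.testing.assert_allclose(s1.variance, s2.variance, atol=1e-15)
        for p in (10, 50, 90):
            np.testing.assert_array_equal(reject_uncertain(t1, s1, p),
                                          reject_uncertain(t2, s2, p))

    def test_per_subject_scope(self):
        sids = np.array(["a"] * 4 + ["b"] * 4, dtype=object)
        rows = np.array([[0.5] * 4 + [0.0] * 4,
                         [0.5] * 4 + [1.0] * 4])   # all variance lives in b
        t = tensor_of(rows, sids)
        s = epoch_variance(t)
        kept = reject_uncertain(t, s, 50)
        # per-subject: each subject loses its own half
        assert (np.asarray(sids)[kept] == "a").sum() == 2
        assert (np.asarray(sids)[kept] == "b").sum() == 2
        pooled = reject_uncertain(t, s, 50, pooled=True)
        assert (np.asarray(sids)[pooled] == "a").sum() == 4
        assert (np.asarray(sids)[pooled] == "b").sum() == 0

    def test_invalid_p_rejected(self):
        t = tensor_of(np.full((2, 4), 0.5))
        s = epoch_variance(t)
        for p in (-1, 100, 150):
            with pytest.raises(ConfigurationError):
                reject_uncertain(t, s, p)


class TestErrorDecrease:
    def test_worked_values(self):
        assert error_decrease(90.0, 95.0) == pytest.approx(50.0)
        assert error_decrease(90.0, 90.0) == 0.0
        assert error_decrease(86.6, 90.9) == pytest.approx(32.09, abs=0.005)

    def test_perfect_before_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            error_decrease(100.0, 100.0)

    def test_range_checked(self):
        with pytest.raises(ValueError):
            error_decrease(110.0, 90.0)


class TestRejectionCurve:
    def labels_for(self, sids):
        return {s: 1 for s in dict.fromkeys(sids)}

    def test_one_row_per_grid_point(self):
        rng = np.random.default_rng(5)
        sids = np.repeat(["a", "b"], 10).astype(object)
        t = tensor_of(rng.random((3, 20)), sids)
        curve = rejection_curve(t, {"a": 1, "b": 0})
        assert list(curve["p_removed"]) == list(DEFAULT_P_GRID)
        assert curve["n_epochs_kept"].is_monotonic_decreasing

    def test_degenerate_identical_members_constant_accuracy(self):
        sids = np.repeat(["a", "b"], 8).astype(object)
        row = np.array([0.9] * 8 + [0.2] * 8)
        t = tensor_of(np.tile(row, (3, 1)), sids)
        curve = rejection_curve(t, {"a": 1, "b": 0})
        assert curve["per_subject_accuracy"].nunique() == 1

    def test_rejecting_high_variance_errors_improves_accuracy(self):
        """Fixture where the disagreeing epochs are exactly the wrongly
        predicted ones: accuracy at p=50 must not be below p=0."""
        rng = np.random.default_rng(6)
        sids = np.repeat([f"s{i}" for i in range(6)], 10).astype(object)
        labels = {f"s{i}": 1 for i in range(6)}
        probs = np.full((4, 60), 0.9)
        wrong = rng.choice(60, size=30, replace=False)
        for j in wrong:     # high-variance and wrong on average
            probs[:, j] = [0.05, 0.15, 0.35, 0.85]
        t = tensor_of(probs, sids)
        curve = rejection_curve(t, labels).set_index("p_removed")
        assert curve.loc[50, "per_subject_accuracy"] >= \
            curve.loc[0, "per_subject_accuracy"]

    def test_disagreement_unrelated_to_correctness_changes_nothing_on_average(self):
        """When variance is independent of correctness, the expected accuracy
        change from rejection is zero (Monte Carlo over 200 resamples)."""
        deltas = []
        for seed in range(200):
            rng = np.random.default_rng(1000 + seed)
            sids = np.repeat([f"s{i}" for i in range(8)], 6).astype(object)
            labels = {f"s{i}": int(rng.integers(0, 2)) for i in range(8)}
            centre = rng.random(48)             # independent of labels
            spread = rng.uniform(0, 0.1, 48)    # variance independent too
            probs = np.clip(centre + np.outer([-1, 0, 1], spread), 0, 1)
            t = tensor_of(probs, sids)
            curve = rejection_curve(t, labels).set_index("p_removed")
            deltas.append(curve.loc[50, "per_subject_accuracy"]
                          - curve.loc[0, "per_subject_accuracy"])
        assert abs(np.mean(deltas)) < 6.0

    def test_all_epochs_removed_falls_back_and_flags(self):
        """Per-subject rejection always keeps at least one epoch (floor
        count), but pooled rejection can empty a subject: it must then fall
        back to its full-epoch prediction and be flagged."""
        sids = np.array(["a"] * 4 + ["b"] * 4, dtype=object)
        probs = np.array([[0.9] * 4 + [0.1] * 4,
                          [0.9] * 4 + [0.9] * 4])   # all variance in b
        t = tensor_of(probs, sids)
        curve = rejection_curve(t, {"a": 1, "b": 1}, p_grid=(0, 50),
                                pooled=True).set_index("p_removed")
        assert curve.loc[50, "n_epochs_kept"] == 4
        assert curve.loc[50, "n_fallback_subjects"] == 1
        assert curve.loc[50, "per_subject_accuracy"] == \
            curve.loc[0, "per_subject_accuracy"]

    def test_empty_grid_rejected(self):
        t = tensor_of(np.full((2, 4), 0.5))
        with pytest.raises(ConfigurationError):
            rejection_curve(t, {"s": 1}, p_grid=())


class TestTable3Summary:
    def frame(self, cells):
        return pd.DataFrame([{"ensemble": e, "fold": f, "p_removed": p,
                              "decrease": d} for (e, f, p, d) in cells])

    def test_single_cell_all_aggregates_equal(self):
        out = summarize_table3(self.frame([("e1", 0, 10, 7.5)]))
        row = out.iloc[0]
        assert row["avg_error_decrease"] == row["avg_max_error_decrease"] \
            == row["max_error_decrease"] == 7.5
        assert row["pct_kept_epochs"] == 90

    def test_avg_max_is_mean_of_per_ensemble_maxima(self):
        cells = [("e1", 0, 10, 5.0), ("e1", 1, 10, 10.0),
                 ("e2", 0, 10, 20.0), ("e2", 1, 10, 0.0)]
        out = summarize_table3(self.frame(cells)).iloc[0]
        assert out["avg_error_decrease"] == pytest.approx(8.75)
        assert out["avg_max_error_decrease"] == pytest.approx(15.0)
        assert out["max_error_decrease"] == pytest.approx(20.0)

    def test_constant_decreases(self):
        cells = [("e1", f, p, 3.0) for f in range(3) for p in (10, 25)]
        out = summarize_table3(self.frame(cells))
        for col in ("avg_error_decrease", "avg_max_error_decrease",
                    "max_error_decrease"):
            assert (out[col] == 3.0).all()

    def test_nan_cells_excluded(self):
        cells = [("e1", 0, 10, 4.0), ("e1", 1, 10, float("nan"))]
        out = summarize_table3(self.frame(cells)).iloc[0]
        assert out["avg_error_decrease"] == 4.0
        assert out["n_cells"] == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_table3(pd.DataFrame(columns=["ensemble", "fold",
                                                   "p_removed", "decrease"]))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(2, 6), st.integers(1, 30), st.integers(0, 2**31 - 1))
def test_variance_oracle_property(m, n, seed):
    rng = np.random.default_rng(seed)
    rows = rng.random((m, n))
    v = epoch_variance(tensor_of(rows)).variance
    np.testing.assert_allclose(v, brute_force_variance(rows), atol=1e-12)
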