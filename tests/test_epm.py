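"""Arm-selectivity score, shuffle null, classification, populations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mazephys.core import (
    EPM_ARM_LABELS,
    CompartmentRates,
    SpikeTrain,
    compartment_rates,
)
from mazephys.epm import (
    CLOSED_PREFERRING,
    NOT_TASK_RELATED,
    OPEN_PREFERRING,
    EPMScoreResult,
    FoldRates,
    UnscorableUnit,
    classify_unit,
    empirical_p_value,
    epm_score,
    fold_rates,
    score_unit,
    shuffle_null,
)

from conftest import make_labelled_trajectory


def _rates(counts, occ, duration=None, n=None):
    """CompartmentRates built from raw tallies."""
    if duration is None:
        duration = sum(occ.values())
    if n is None:
        n = sum(counts.values())
    rates = {
        lab: counts[lab] / occ[lab] if occ[lab] > 0 else np.nan
        for lab in counts
    }
    return CompartmentRates(
        "u", dict(occ), dict(counts), rates, n / duration, n, duration
    )


ARM_OCC = {lab: 100.0 for lab in EPM_ARM_LABELS}


class TestFoldRates:
    def test_worked_example_left_arm_twice_mean(self):
        # unit at 4 Hz overall firing 8 Hz in the left closed arm
        occ = dict(ARM_OCC, center=200.0)
        counts = {
            "closed_left": 800, "closed_right": 400,
            "open_up": 400, "open_down": 400, "center": 400,
        }
        f = fold_rates(_rates(counts, occ))  # mean = 2400/600 = 4 Hz
        assert f.left == pytest.approx(2.0)

    def test_uniform_unit_folds_are_one(self):
        counts = {lab: 400 for lab in ARM_OCC}
        f = fold_rates(_rates(counts, ARM_OCC))
        assert f.as_array() == pytest.approx(np.ones(4))

    def test_silent_arm_fold_zero(self):
        counts = {
            "closed_left": 0, "closed_right": 400,
            "open_up": 400, "open_down": 400,
        }
        assert fold_rates(_rates(counts, ARM_OCC)).left == 0.0

    def test_zero_mean_rate_unscorable(self):
        counts = {lab: 0 for lab in ARM_OCC}
        with pytest.raises(UnscorableUnit):
            fold_rates(_rates(counts, ARM_OCC))

    def test_unvisited_arm_unscorable(self):
        occ = dict(ARM_OCC, open_down=0.0)
        counts = {lab: 10 for lab in ARM_OCC}
        with pytest.raises(UnscorableUnit):
            fold_rates(_rates(counts, occ))


class TestScore:
    def test_pure_arm_type_coding_scores_one(self):
        score, a, b = epm_score(FoldRates(2, 2, 0, 0))
        assert (score, a, b) == (1.0, 2.0, 0.0)

    def test_uniform_rates_score_zero_by_convention(self):
        score, a, b = epm_score(FoldRates(1, 1, 1, 1))
        assert (score, a, b) == (0.0, 0.0, 0.0)

    def test_within_type_selectivity_scores_negative(self):
        # hand evaluation: A = 0.5, B = 1 -> score = -1/3
        score, a, b = epm_score(FoldRates(2, 1, 2, 1))
        assert a == pytest.approx(0.5)
        assert b == pytest.approx(1.0)
        assert score == pytest.approx(-1.0 / 3.0)

    folds = st.floats(0.0, 50.0, allow_nan=False)

    @settings(max_examples=200, derandomize=True)
    @given(folds, folds, folds, folds)
    def test_score_bounded(self, fl, fr, fu, fd):
        score, _, _ = epm_score(FoldRates(fl, fr, fu, fd))
        assert -1.0 <= score <= 1.0

    @settings(max_examples=100, derandomize=True)
    @given(folds, folds, folds, folds, st.floats(0.01, 100.0))
    def test_scale_invariance(self, fl, fr, fu, fd, c):
        s1, _, _ = epm_score(FoldRates(fl, fr, fu, fd))
        s2, _, _ = epm_score(FoldRates(c * fl, c * fr, c * fu, c * fd))
        assert s2 == pytest.approx(s1, abs=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(folds, folds, folds, folds)
    def test_label_symmetry(self, fl, fr, fu, fd):
        s0, _, _ = epm_score(FoldRates(fl, fr, fu, fd))
        for swapped in [
            FoldRates(fr, fl, fu, fd),   # left <-> right
            FoldRates(fl, fr, fd, fu),   # up <-> down
            FoldRates(fu, fd, fl, fr),   # closed pair <-> open pair
        ]:
            s, _, _ = epm_score(swapped)
            assert s == pytest.approx(s0, abs=1e-12)


class TestShuffleNull:
    def test_default_ensemble_size_is_500(self, epm_trajectory):
        null = shuffle_null(50, epm_trajectory, rng=0)
        assert null.shape == (500,)

    def test_same_seed_identical_ensemble(self, epm_trajectory):
        a = shuffle_null(80, epm_trajectory, reps=50, rng=3)
        b = shuffle_null(80, epm_trajectory, reps=50, rng=3)
        np.testing.assert_array_equal(a, b)

    def test_more_spikes_than_samples_rejected(self):
        traj = make_labelled_trajectory(
            ["closed_left", "closed_right", "open_up", "open_down"] * 5
        )
        with pytest.raises(ValueError):
            shuffle_null(100, traj, rng=0)

    def test_matches_direct_timestamp_draw(self, epm_trajectory):
        """Hypergeometric count sampling reproduces the distribution of
        scores from literally drawing timestamps without replacement."""
        from scipy.stats import ks_2samp

        from mazephys.epm import _scores_from_arm_counts

        n_spikes, reps = 120, 1500
        labels = np.asarray(epm_trajectory.labels)
        dt = epm_trajectory.sample_interval
        rng = np.random.default_rng(42)
        direct = []
        arm_occ = np.array(
            [np.count_nonzero(labels == l) for l in EPM_ARM_LABELS],
            dtype=float,
        ) * dt
        mean_rate = n_spikes / epm_trajectory.session_duration
        for _ in range(reps):
            pick = rng.choice(labels.size, size=n_spikes, replace=False)
            chosen = labels[pick]
            counts = np.array(
                [np.count_nonzero(chosen == l) for l in EPM_ARM_LABELS],
                dtype=float,
            )
            direct.append(
                _scores_from_arm_counts(counts[None, :], arm_occ, mean_rate)[0]
            )
        fast = shuffle_null(n_spikes, epm_trajectory, reps=reps, rng=43)
        assert ks_2samp(np.asarray(direct), fast).pvalue > 0.01

    def test_empirical_p_add_one_estimator(self):
        null = np.array([0.1, 0.2, 0.3, 0.4])
        assert empirical_p_value(0.35, null) == pytest.approx(2 / 5)
        assert empirical_p_value(0.9, null) == pytest.approx(1 / 5)


class TestClassification:
    def _result(self, score):
        return EPMScoreResult("u", FoldRates(1, 1, 1, 1), 0, 0, score)

    def _cr(self, closed, open_):
        counts = {
            "closed_left": closed, "closed_right": closed,
            "open_up": open_, "open_down": open_,
        }
        return _rates(counts, ARM_OCC)

    def test_negative_score_not_task_related(self):
        assert classify_unit(self._result(-0.2), self._cr(600, 200)) == (
            NOT_TASK_RELATED
        )

    def test_zero_score_not_task_related(self):
        assert classify_unit(self._result(0.0), self._cr(600, 200)) == (
            NOT_TASK_RELATED
        )

    def test_positive_score_closed_dominant(self):
        assert classify_unit(self._result(0.6), self._cr(600, 200)) == (
            CLOSED_PREFERRING
        )

    def test_positive_score_open_dominant(self):
        assert classify_unit(self._result(0.6), self._cr(200, 600)) == (
            OPEN_PREFERRING
        )

    def test_exact_rate_tie_conservative(self):
        assert classify_unit(self._result(0.6), self._cr(300, 300)) == (
            NOT_TASK_RELATED
        )


def test_score_unit_end_to_end_matches_manual_recomputation(epm_trajectory):
    """score_unit agrees with recomputing every step from raw tallies."""
    rng = np.random.default_rng(11)
    spikes = SpikeTrain("u", np.sort(rng.uniform(0, 1200.0, 900)), 1200.0)
    res = score_unit(spikes, epm_trajectory, reps=100, rng=5)

    cr = compartment_rates(spikes, epm_trajectory)
    fold = {
        lab: cr.rates[lab] / cr.mean_rate for lab in EPM_ARM_LABELS
    }
    fl, fr = fold["closed_left"], fold["closed_right"]
    fu, fd = fold["open_up"], fold["open_down"]
    a = 0.25 * (abs(fl - fu) + abs(fl - fd) + abs(fr - fu) + abs(fr - fd))
    b = 0.5 * (abs(fl - fr) + abs(fu - fd))
    assert res.score == pytest.approx((a - b) / (a + b))
    assert res.a == pytest.approx(a)
    assert res.b == pytest.approx(b)
    assert res.null_scores.shape == (100,)
    assert 0 < res.empirical_p <= 1
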