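"""Weight-profile, correlation and convergence metrics on constructed data."""

import numpy as np
import pytest

from cereblearn.analysis import (
    averaged_gain,
    convergence_trial,
    counter_phase_score,
    error_reduction_pct,
    reverse_cross_correlation,
    two_timescale_check,
    weight_profile,
)
from cereblearn.coding import build_state_schedule


@pytest.fixture(scope="module")
def gc_schedule():
    return build_state_schedule(2000, 4, 1.0, 0.002)


@pytest.fixture(scope="module")
def mf_schedule():
    return build_state_schedule(100, 4, 1.0, 0.002)


class TestWeightProfile:
    def test_uniform_weights_give_flat_profile(self, gc_schedule):
        w = np.full((2000, 10), 5.0)
        prof = weight_profile(w, gc_schedule)
        assert prof.mean_weight.shape == (500,)
        assert np.all(prof.mean_weight == 5.0)

    def test_single_depressed_state_shows_single_dip(self, gc_schedule):
        w = np.full((2000, 10), 5.0)
        w[gc_schedule.assignment[123], :] = 1.0
        prof = weight_profile(w, gc_schedule)
        assert prof.mean_weight.argmin() == 123
        assert np.sum(prof.mean_weight < 5.0) == 1

    def test_mf_profile_has_25_states(self, mf_schedule):
        prof = weight_profile(np.zeros((100, 2)), mf_schedule, columns=[0])
        assert len(prof.mean_weight) == 25

    def test_mismatched_rows_rejected(self, gc_schedule):
        with pytest.raises(ValueError):
            weight_profile(np.zeros((10, 2)), gc_schedule)


class TestCounterPhase:
    def test_negation_scores_minus_one(self, rng):
        a = rng.normal(0, 1, 500)
        b = -a.reshape(25, 20).mean(axis=1)
        assert counter_phase_score(a, b) == pytest.approx(-1.0)

    def test_self_scores_plus_one(self, rng):
        a = rng.normal(0, 1, 500)
        b = a.reshape(25, 20).mean(axis=1)
        assert counter_phase_score(a, b) == pytest.approx(1.0)

    def test_sign_symmetries(self, rng):
        a = rng.normal(0, 1, 500)
        b = rng.normal(0, 1, 25)
        s = counter_phase_score(a, b)
        assert counter_phase_score(-a, -b) == pytest.approx(s)
        assert counter_phase_score(-a, b) == pytest.approx(-s)

    def test_zero_variance_reported_as_nan(self):
        assert np.isnan(counter_phase_score(np.ones(500), np.arange(25.0)))

    def test_incompatible_lengths_rejected(self):
        with pytest.raises(ValueError):
            counter_phase_score(np.ones(500), np.ones(23))


class TestReverseCrossCorrelation:
    def test_complementary_trains_score_near_one(self, rng):
        # DCN fires exactly in the bins where the PC is silent
        bins = rng.random(200) < 0.5
        pc = np.flatnonzero(bins) * 0.01 + 0.005
        dcn = np.flatnonzero(~bins) * 0.01 + 0.005
        res = reverse_cross_correlation(pc, dcn, bin_width=0.01, max_lag=0.05)
        assert res.summary == pytest.approx(1.0, abs=0.01)

    def test_identical_trains_minimize_summary(self, rng):
        t = np.sort(rng.uniform(0, 2, 200))
        res = reverse_cross_correlation(t, t, bin_width=0.01, max_lag=0.05)
        # identical trains are maximally correlated, hence the
        # anti-correlation summary is as small as it can be
        assert res.correlation[res.lags == 0][0] == pytest.approx(1.0)
        assert res.summary < 0.5

    def test_independent_poisson_trains_near_null(self, rng):
        pc = np.sort(rng.uniform(0, 10, 800))
        dcn = np.sort(rng.uniform(0, 10, 500))
        res = reverse_cross_correlation(pc, dcn, bin_width=0.01, max_lag=0.1)
        # permutation null: max |r| over 21 lags for ~1000 bins
        null = []
        counts, _ = np.histogram(dcn, np.arange(0, 10.01, 0.01))
        a, _ = np.histogram(pc, np.arange(0, 10.01, 0.01))
        for _ in range(200):
            b = rng.permutation(counts)
            null.append(abs(np.corrcoef(a, b)[0, 1]))
        thresh = np.mean(null) + 3 * np.std(null) + 21 ** 0.5 * np.std(null)
        assert res.summary < 0.1 + thresh

    def test_bounded_by_one(self, rng):
        res = reverse_cross_correlation(
            np.sort(rng.uniform(0, 1, 60)), np.sort(rng.uniform(0, 1, 60)),
            bin_width=0.02, max_lag=0.1,
        )
        valid = res.correlation[~np.isnan(res.correlation)]
        assert np.all(np.abs(valid) <= 1 + 1e-12)

    def test_empty_train_undefined(self):
        with pytest.raises(ValueError):
            reverse_cross_correlation([], [0.1, 0.2])


class TestAveragedGain:
    def test_trivial_means(self):
        assert averaged_gain(np.zeros(10)) == 0.0
        assert averaged_gain(np.full(10, 2.5)) == 2.5
        w = np.array([0.0] * 5 + [3.0] * 5)
        assert averaged_gain(w) == 1.5
        assert averaged_gain(w, indices=range(5, 10)) == 3.0


class TestConvergenceTrial:
    def test_constant_series_converges_immediately(self):
        assert convergence_trial(np.full(1000, 3.3)) == 0

    def test_step_series_converges_at_jump(self):
        x = np.concatenate([np.zeros(400), np.ones(600)])
        t = convergence_trial(x, window=50)
        assert 350 <= t <= 450

    def test_exponential_settles_near_three_time_constants(self):
        tau = 300.0
        n = np.arange(5000)
        x = 1.0 - np.exp(-n / tau)
        t = convergence_trial(x, fraction=0.05, window=50)
        assert t == pytest.approx(3 * tau, rel=0.25)

    def test_drifting_series_not_converged(self):
        x = np.arange(2000.0)  # never settles inside the final band
        t = convergence_trial(x, fraction=0.01, window=1)
        assert t is None or t > 1900

    def test_validation(self):
        with pytest.raises(ValueError):
            convergence_trial([])
        with pytest.raises(ValueError):
            convergence_trial([1.0], fraction=1.5)


class TestErrorReduction:
    def test_identical_windows_zero(self):
        x = np.ones(100) * 2
        assert error_reduction_pct(x, (0, 10), (90, 100)) == 0.0

    def test_perfect_final_hundred_pct(self):
        x = np.concatenate([np.full(10, 2.0), np.zeros(90)])
        assert error_reduction_pct(x, (0, 10), (90, 100)) == 100.0

    def test_arithmetic(self):
        x = np.concatenate([np.full(10, 2.0), np.full(90, 0.5)])
        assert error_reduction_pct(x, (0, 10), (90, 100)) == pytest.approx(75.0)

    def test_never_exceeds_hundred(self, rng):
        x = np.abs(rng.normal(1, 0.5, 200)) + 1e-6
        assert error_reduction_pct(x, (0, 20), (180, 200)) <= 100.0

    def test_zero_baseline_undefined(self):
        with pytest.raises(ValueError):
            error_reduction_pct(np.zeros(10), (0, 5), (5, 10))


class TestTwoTimescale:
    def test_ordered_exponentials(self):
        n = np.arange(6000)
        fast = 1 - np.exp(-n / 100)
        mid = 1 - np.exp(-n / 500)
        slow = 1 - np.exp(-n / 1000)
        res = two_timescale_check(fast, mid, slow)
        assert res["ordered"]
        assert res["pfpc"] < res["mfdcn"] <= res["pcdcn"]

    def test_all_constant_is_a_tie_not_a_pass(self):
        x = np.ones(1000)
        res = two_timescale_check(x, x, x)
        assert not res["ordered"]
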