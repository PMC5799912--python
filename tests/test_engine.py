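import numpy as np
import pytest

import crmkit as ck
from crmkit.engine import A_GRID

from .conftest import importance_posterior, weighted_quantile


def random_small_states(K: int, count: int, seed: int = 13):
    """Battery of random small trials: a few cohorts of data somewhere."""
    rng = np.random.default_rng(seed)
    states = []
    for _ in range(count):
        n = rng.integers(0, 7, size=K)
        if n.sum() == 0:
            n[rng.integers(K)] = 2
        y = np.array([rng.integers(0, nk + 1) for nk in n])
        tried = np.flatnonzero(n)
        states.append(
            ck.TrialState(y=tuple(y), n=tuple(n), current_dose=int(tried[-1]) + 1)
        )
    return states


class TestLogLikelihood:
    def test_empty_data_is_flat(self, default_design, skeleton5):
        state = ck.TrialState.empty(5)
        for a in (-3.0, 0.0, 2.5):
            assert ck.log_likelihood(a, state, skeleton5) == 0.0

    def test_single_dlt_at_prior_mean(self, skeleton5):
        state = ck.TrialState(y=(0, 1, 0, 0, 0), n=(0, 1, 0, 0, 0), current_dose=2)
        assert ck.log_likelihood(0.0, state, skeleton5) == pytest.approx(
            np.log(skeleton5[1])
        )

    def test_two_non_dlts_hand_computed(self, skeleton5):
        state = ck.TrialState(y=(0, 0, 0, 0, 0), n=(2, 0, 0, 0, 0), current_dose=1)
        expected = 2.0 * np.log(1.0 - skeleton5[0])
        assert ck.log_likelihood(0.0, state, skeleton5) == pytest.approx(expected)

    def test_floor_to_neg_inf_when_probability_saturates(self):
        # alpha**exp(a) underflows to 1 for very negative a; with observed
        # non-DLTs the likelihood must floor, not raise
        state = ck.TrialState(y=(0,), n=(2,), current_dose=1)
        val = ck.log_likelihood(-40.0, state, np.array([0.9999]))
        assert val == -np.inf


class TestPosterior:
    def test_empty_data_returns_prior_mean(self, default_design):
        state = ck.TrialState.empty(5)
        assert ck.posterior_mean_a(state, default_design) == pytest.approx(0.0, abs=1e-8)

    def test_quadrature_matches_sampling_oracle(self, default_design):
        for state in random_small_states(5, 6):
            quad = ck.posterior_mean_a(state, default_design)
            _, _, mc, se = importance_posterior(state, default_design)
            assert abs(quad - mc) <= max(3 * se, 1e-4)

    def test_halving_grid_step_is_converged(self, default_design):
        state = ck.TrialState(y=(0, 0, 1, 0, 0), n=(2, 2, 4, 0, 0), current_dose=3)
        coarse = ck.posterior_mean_a(state, default_design, np.linspace(-10, 10, 1001))
        fine = ck.posterior_mean_a(state, default_design, A_GRID)
        assert abs(coarse - fine) < 1e-6

    def test_plug_in_identity_at_zero(self, skeleton5):
        assert np.allclose(ck.estimate_dlt_probs(0.0, skeleton5), skeleton5)

    def test_plug_in_limits(self, skeleton5):
        assert np.all(ck.estimate_dlt_probs(8.0, skeleton5) < 1e-3)
        assert np.all(ck.estimate_dlt_probs(-8.0, skeleton5) > 0.999)

    def test_monotone_data_response(self, default_design, skeleton5):
        # one extra DLT anywhere raises every estimate; one extra non-DLT
        # lowers every estimate
        for state in random_small_states(5, 5, seed=99):
            p0 = ck.estimate_dlt_probs(
                ck.posterior_mean_a(state, default_design), skeleton5
            )
            for dose in range(1, 6):
                more_tox = state.with_cohort(dose, 1, 1)
                more_tox = ck.TrialState(
                    y=more_tox.y, n=more_tox.n, current_dose=state.current_dose
                )
                p_tox = ck.estimate_dlt_probs(
                    ck.posterior_mean_a(more_tox, default_design), skeleton5
                )
                assert np.all(p_tox >= p0 - 1e-12)
                more_safe = state.with_cohort(dose, 1, 0)
                p_safe = ck.estimate_dlt_probs(
                    ck.posterior_mean_a(more_safe, default_design), skeleton5
                )
                assert np.all(p_safe <= p0 + 1e-12)

    def test_estimates_preserve_skeleton_ordering(self, skeleton5):
        for a_hat in (-2.0, -0.3, 0.0, 0.7, 3.0):
            p = ck.estimate_dlt_probs(a_hat, skeleton5)
            assert np.all(np.diff(p) > 0)


class TestRecommendDose:
    def test_no_skip_caps_escalation(self):
        state = ck.TrialState(y=(0, 0, 0, 0, 0), n=(2, 0, 0, 0, 0), current_dose=1)
        p_hat = np.array([0.06, 0.12, 0.21, 0.31, 0.42])  # argmin at dose 3
        assert ck.recommend_dose(p_hat, 0.25, state) == 2

    def test_deescalation_unrestricted(self):
        state = ck.TrialState(y=(0, 0, 2, 0, 0), n=(0, 0, 2, 0, 0), current_dose=3)
        p_hat = np.array([0.24, 0.5, 0.7, 0.8, 0.9])
        assert ck.recommend_dose(p_hat, 0.25, state) == 1

    def test_ties_break_to_lower_dose(self):
        state = ck.TrialState(y=(0, 0, 0), n=(0, 2, 0), current_dose=2)
        p_hat = np.array([0.20, 0.30, 0.60])  # doses 1 and 2 equidistant
        assert ck.recommend_dose(p_hat, 0.25, state) == 1

    def test_never_more_than_one_level_above_current(self, default_design, skeleton5):
        for state in random_small_states(5, 8, seed=5):
            p = ck.estimate_dlt_probs(
                ck.posterior_mean_a(state, default_design), skeleton5
            )
            assert ck.recommend_dose(p, 0.25, state) <= state.current_dose + 1


class TestSafetyCheck:
    def test_vague_prior_does_not_stop(self, default_design, skeleton5):
        stop, (lo, hi) = ck.safety_check(ck.TrialState.empty(5), default_design)
        assert not stop
        assert lo < skeleton5[0] < hi

    def test_all_dlts_at_lowest_dose_stops(self, default_design):
        state = ck.TrialState(y=(20, 0, 0, 0, 0), n=(20, 0, 0, 0, 0), current_dose=1)
        stop, (lo, _) = ck.safety_check(state, default_design)
        assert stop and lo > default_design.theta
        # sampling oracle: the 5th posterior percentile of R(d1) exceeds theta
        a, w, _, _ = importance_posterior(state, default_design)
        p1 = default_design.skeleton[0] ** np.exp(a)
        assert weighted_quantile(p1, w, 0.05) > default_design.theta

    def test_interval_matches_sampling_oracle(self, default_design):
        for state in random_small_states(5, 4, seed=77):
            _, (lo, hi) = ck.safety_check(state, default_design)
            a, w, _, _ = importance_posterior(state, default_design)
            p1 = default_design.skeleton[0] ** np.exp(a)
            assert lo == pytest.approx(weighted_quantile(p1, w, 0.05), abs=0.01)
            assert hi == pytest.approx(weighted_quantile(p1, w, 0.95), abs=0.01)


class TestNextAction:
    def test_empty_state_assigns_starting_dose(self, default_design):
        rec = ck.next_action(ck.TrialState.empty(5), default_design)
        assert rec.dose == default_design.start_dose
        assert rec.stop_reason is None

    def test_sequential_worked_path(self, default_design):
        # 0/2 at dose 1 -> escalate to 2; plus 0/2 at dose 2 -> 3; plus
        # 1/4 at dose 3 -> stay at 3
        s1 = ck.TrialState(y=(0,) * 5, n=(2, 0, 0, 0, 0), current_dose=1)
        assert ck.next_action(s1, default_design).dose == 2
        s2 = s1.with_cohort(2, 2, 0)
        assert ck.next_action(s2, default_design).dose == 3
        s3 = s2.with_cohort(3, 4, 1)
        assert ck.next_action(s3, default_design).dose == 3

    def test_deterministic_in_data_with_audit_timestamp(self, default_design):
        state = ck.TrialState(y=(0, 1, 0, 0, 0), n=(2, 2, 0, 0, 0), current_dose=2)
        r1, r2 = ck.next_action(state, default_design), ck.next_action(state, default_design)
        assert r1.dose == r2.dose
        assert r1.posterior == r2.posterior
        assert r1.timestamp  # ISO-8601 wall clock, audit only

    def test_safety_stop_reported(self, default_design):
        state = ck.TrialState(y=(6, 0, 0, 0, 0), n=(6, 0, 0, 0, 0), current_dose=1)
        rec = ck.next_action(state, default_design)
        assert rec.dose is None and rec.stop_reason == "safety"


class TestStateValidation:
    @pytest.mark.parametrize(
        "y,n,cd",
        [((3, 0), (2, 0), 1), ((-1, 0), (2, 0), 1), ((0, 0), (2, 0), 3)],
    )
    def test_inconsistent_counts_rejected(self, y, n, cd):
        with pytest.raises(ck.InvalidStateError):
            ck.TrialState(y=y, n=n, current_dose=cd)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(theta=0.25, skeleton=(0.3, 0.2), sigma_a=0.5),
            dict(theta=0.25, skeleton=(0.1, 0.2), sigma_a=-1.0),
            dict(theta=0.25, skeleton=(0.1, 0.2), sigma_a=0.5, cohort_size=4),
            dict(theta=0.25, skeleton=(0.1, 0.2), sigma_a=0.5, max_n=25, cohort_size=2),
            dict(theta=0.25, skeleton=(0.1, 0.2), sigma_a=0.5, start_dose=3),
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(ck.InvalidDesignError):
            ck.DesignSpec(**kwargs)
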