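"""Rescorla-Wagner family: update rules, likelihood, fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paralearn.blocking import (
    RWParams,
    SIGMA2_FLOOR,
    VARIANTS,
    WeightState,
    apply_phase_decay,
    fit_participant,
    log_likelihood,
    predict_response,
    run_model,
    update_weights,
)
from paralearn.tasks import TrialTypeSpec, build_blocking_design, emit_trials, first_probe_index


def _params(alpha=0.5, gamma=1.0, lam=0.0, eta=1.0, sigma=None):
    return RWParams(alpha=alpha, gamma=gamma, lam=lam, eta=eta, sigma=sigma)


class TestPrediction:
    def test_single_cue_returns_weight(self):
        s = WeightState({"A": 0.8})
        assert predict_response(s, ("A",), gamma=0.3) == 0.8

    def test_additive_limit_clips(self):
        s = WeightState({"A": 0.5, "B": 0.5})
        assert predict_response(s, ("A", "B"), gamma=1.0) == 1.0

    def test_maximum_only_limit(self):
        s = WeightState({"A": 0.5, "B": 0.3})
        assert predict_response(s, ("A", "B"), gamma=0.0) == 0.5

    def test_empty_cue_set_rejected(self):
        with pytest.raises(ValueError):
            predict_response(WeightState(), (), gamma=0.5)


class TestUpdate:
    def test_single_cue_delta_step(self):
        s = update_weights(WeightState(), ("A",), 1, _params(alpha=0.5))
        assert s.get("A") == 0.5

    def test_blocking_at_zero_asymptote(self):
        s = WeightState({"A": 1.0, "B": 0.0})
        out = update_weights(s, ("A", "B"), 1, _params(alpha=0.5, lam=0.0))
        assert out.get("A") == 1.0 and out.get("B") == 0.0

    def test_counterfactual_step(self):
        s = WeightState({"A": 1.0, "B": 0.0})
        out = update_weights(s, ("A", "B"), 1, _params(alpha=0.5, lam=-1.0))
        assert out.get("B") == -0.5

    def test_invalid_outcome_rejected(self):
        with pytest.raises(ValueError, match="outcome"):
            update_weights(WeightState(), ("A",), 0, _params())

    def test_phase_decay(self):
        s = WeightState({"A": 0.6})
        assert apply_phase_decay(s, 1.0).get("A") == 0.6
        assert apply_phase_decay(s, 0.0).get("A") == 0.0
        assert apply_phase_decay(s, 0.5).get("A") == pytest.approx(0.3)

    @settings(max_examples=50, derandomize=True)
    @given(alpha=st.floats(0.07, 1.0), lam=st.floats(-1.0, 1.0))
    def test_asymptote_property(self, alpha, lam):
        """Repeated compound trials drive w_p -> o and w_s -> lam*o.

        Convergence is geometric at rate (1 - alpha), so 200 iterations
        reach 1e-6 only for alpha above ~0.07 ((1-a)^200 < 1e-6).
        """
        p = _params(alpha=alpha, lam=lam)
        s = WeightState({"A": 0.2, "B": 0.0})  # A pretrained, stays primary
        for _ in range(200):
            s = update_weights(s, ("A", "B"), 1, p)
        assert abs(s.get("A") - 1.0) < 1e-6
        assert abs(s.get("B") - lam) < 1e-6


class TestTrajectory:
    def test_single_cue_geometric_approach(self):
        tt = (TrialTypeSpec("t", (("A",), ("A",), ("A",)), (1, 1, 1)),)
        trials = emit_trials(build_blocking_design(tt, reps_per_phase=(4, 1, 1)))
        traj = run_model(trials[:4], _params(alpha=0.5), "RW3")
        assert np.allclose(traj.predictions, [0.0, 0.5, 0.75, 0.875])

    def test_blocked_cue_stays_naive_at_lam_zero(self, default_trials):
        traj = run_model(default_trials, _params(alpha=0.4, lam=0.0, eta=1.0), "RW2")
        i = first_probe_index(default_trials, "block_confirm")
        assert abs(traj.predictions[i]) < 0.05

    def test_unselective_learning_reaches_derived_value(self, default_trials):
        # six compound pairings at alpha=0.3 with full attribution
        traj = run_model(default_trials, _params(alpha=0.3, lam=1.0, eta=1.0), "RW2")
        i = first_probe_index(default_trials, "block_confirm")
        assert traj.predictions[i] == pytest.approx(1 - 0.7**6, abs=1e-9)

    def test_variant_nesting_bit_equality(self, default_trials):
        base = dict(alpha=0.37, lam=-0.21, eta=0.66)
        rw2_add = run_model(default_trials, _params(gamma=1.0, **base), "RW2")
        rw4 = run_model(default_trials, _params(gamma=1.0, **base), "RW4")
        assert np.array_equal(rw2_add.predictions, rw4.predictions)
        rw2_max = run_model(default_trials, _params(gamma=0.0, **base), "RW2")
        rw5 = run_model(default_trials, _params(gamma=0.0, **base), "RW5")
        assert np.array_equal(rw2_max.predictions, rw5.predictions)
        p3 = _params(alpha=0.37, gamma=0.5, lam=-0.21, eta=1.0)
        rw2_noforget = run_model(default_trials, p3, "RW2")
        rw3 = run_model(default_trials, p3, "RW3")
        assert np.array_equal(rw2_noforget.predictions, rw3.predictions)

    def test_blocking_score_monotone_in_lam(self, default_trials):
        scores = []
        i = first_probe_index(default_trials, "block_confirm")
        for lam in np.linspace(-1, 1, 9):
            traj = run_model(default_trials, _params(alpha=0.35, lam=lam, eta=0.8), "RW2")
            scores.append(traj.predictions[i])
        assert np.all(np.diff(scores) >= -1e-12)


class TestLikelihood:
    def test_constant_residual_closed_form(self):
        n, c = 20, 0.3
        ll = log_likelihood(np.full(n, c), np.zeros(n), "RW2")
        assert ll == pytest.approx(-n / 2 * (math.log(2 * math.pi * c**2) + 1))

    def test_perfect_fit_hits_variance_floor(self):
        r = np.linspace(-1, 1, 10)
        ll = log_likelihood(r, r, "RW2")
        assert np.isfinite(ll)
        assert ll == pytest.approx(-5 * math.log(2 * math.pi * SIGMA2_FLOOR))

    def test_free_sigma_standard_normal(self):
        n = 8
        ll = log_likelihood(np.zeros(n), np.zeros(n), "RW1", sigma=1.0)
        assert ll == pytest.approx(-n / 2 * math.log(2 * math.pi))

    def test_profiled_equals_sigma_grid_maximum(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            resp = rng.uniform(-1, 1, 30)
            pred = rng.uniform(-1, 1, 30)
            profiled = log_likelihood(resp, pred, "RW2")
            grid = [log_likelihood(resp, pred, "RW1", sigma=s)
                    for s in np.linspace(1e-3, 2.0, 4001)]
            assert profiled == pytest.approx(max(grid), abs=1e-4)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood([], [], "RW2")


class TestFitting:
    def test_noise_free_self_consistency(self, default_trials):
        true = _params(alpha=0.3, gamma=0.6, lam=-0.4, eta=0.85)
        responses = run_model(default_trials, true, "RW2").predictions
        fit = fit_participant(default_trials, responses, "RW2", n_starts=10, seed=0)
        refit = run_model(default_trials, fit.params, "RW2").predictions
        assert np.max(np.abs(refit - responses)) < 1e-3

    def test_constant_zero_responses(self, default_trials):
        responses = np.zeros(len(default_trials))
        fit = fit_participant(default_trials, responses, "RW2", n_starts=10, seed=0)
        assert fit.converged
        # optimum: predictions identically zero (e.g. alpha=0), floor likelihood
        zero_ll = log_likelihood(responses, np.zeros_like(responses), "RW2")
        assert fit.loglik == pytest.approx(zero_ll, abs=1e-6)

    def test_grid_search_oracle_three_trials(self):
        tt = (TrialTypeSpec("t", (("A",), ("A",), ("A",)), (1, 1, 1)),)
        trials = emit_trials(build_blocking_design(tt, reps_per_phase=(1, 1, 1)))
        responses = np.array([0.1, 0.45, 0.6])

        # single-cue task: only alpha and eta shape the trajectory
        def predictions(alpha, eta):
            w = 0.0
            out = []
            for t in trials:
                if t.is_first_of_phase:
                    w *= eta
                out.append(w)
                if t.gives_feedback:
                    w += alpha * (t.outcome - w)
            return np.array(out)

        grid_best = -np.inf
        for a in np.arange(0.0, 1.0001, 0.01):
            for e in np.arange(0.0, 1.0001, 0.01):
                ll = log_likelihood(responses, predictions(a, e), "RW2")
                grid_best = max(grid_best, ll)
        fit = fit_participant(trials, responses, "RW2", n_starts=25, seed=0)
        assert fit.loglik >= grid_best - 1e-3

    def test_seeded_fit_reproduces(self, default_trials):
        rng = np.random.default_rng(3)
        responses = np.clip(rng.normal(0, 0.5, len(default_trials)), -1, 1)
        a = fit_participant(default_trials, responses, "RW2", n_starts=5, seed=42)
        b = fit_participant(default_trials, responses, "RW2", n_starts=5, seed=42)
        assert a.params == b.params and a.loglik == b.loglik

    def test_information_criteria_definitions(self, default_trials):
        responses = np.zeros(len(default_trials))
        fit = fit_participant(default_trials, responses, "RW2", n_starts=3, seed=0)
        n, k = fit.n_trials, fit.n_params
        assert fit.bic == pytest.approx(k * math.log(n) - 2 * fit.loglik)
        assert fit.aic == pytest.approx(2 * k - 2 * fit.loglik)
        assert k == 4 and VARIANTS["RW1"].n_params == 5

    def test_out_of_range_response_names_trial(self, default_trials):
        responses = np.zeros(len(default_trials))
        responses[17] = 1.5
        with pytest.raises(ValueError, match="trial 17"):
            fit_participant(default_trials, responses, "RW2")
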