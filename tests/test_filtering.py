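"""Augmented-state Bayesian filters: prediction, mixed update, reductions."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from arousalctl import (
    AugmentedBelief,
    Observation,
    ObservationParams,
    StateNoiseParams,
    adaptive_model,
    filter_nominal,
    filter_series,
    log_observation_likelihood,
    make_stimulus_schedule,
    predict,
    robust_model,
    simulate_truth,
    update,
)


def belief(mean, cov, track="adaptive") -> AugmentedBelief:
    return AugmentedBelief(mean=np.array(mean), cov=np.array(cov), track=track)


UNIT = ObservationParams(
    gamma=0.0, tonic_intercept=0.0, tonic_slope=1.0, tonic_noise_var=1.0
)


class TestPredict:
    def test_adaptive_mean_propagation(self):
        model = adaptive_model(StateNoiseParams(0.01, gain_walk_var=0.001))
        out = predict(belief([1.0, 0.9], np.eye(2)), 0.0, model)
        np.testing.assert_allclose(out.mean, [0.9, 0.9])

    def test_robust_mean_propagation(self):
        model = robust_model(StateNoiseParams(0.01, disturbance_walk_var=0.001))
        out = predict(belief([1.0, 0.2], np.eye(2), "robust"), 0.1, model)
        np.testing.assert_allclose(out.mean, [1.3, 0.2])

    def test_adaptive_covariance_hand_oracle(self):
        # F = [[0.9, 1], [0, 1]] at mean (1.0, 0.9);
        # F I F' + diag(0.01, 0.001) = [[1.82, 1.0], [1.0, 1.001]]
        model = adaptive_model(StateNoiseParams(0.01, gain_walk_var=0.001))
        out = predict(belief([1.0, 0.9], np.eye(2)), 0.0, model)
        np.testing.assert_allclose(
            out.cov, [[1.82, 1.0], [1.0, 1.001]], atol=1e-12
        )

    def test_track_mismatch_rejected(self):
        model = robust_model(StateNoiseParams(0.01))
        with pytest.raises(ValueError):
            predict(belief([0.0, 1.0], np.eye(2), "adaptive"), 0.0, model)


class TestUpdate:
    def test_worked_mixed_update(self):
        # Unit parameters, identity prior at (0, .), obs (n=1, r=0.5):
        # curvature 1.25 => var 1/2.25 = 4/9; score 1.0 => mean 4/9.
        pred = belief([0.0, 1.0], np.eye(2))
        post = update(pred, Observation(1, 0.5), UNIT)
        assert post.cov[0, 0] == pytest.approx(4.0 / 9.0, abs=1e-12)
        assert post.mean[0] == pytest.approx(4.0 / 9.0, abs=1e-12)

    def test_zero_score_leaves_mean(self):
        # r chosen so the tonic pull cancels the binary pull exactly
        pred = belief([0.0, 1.0], [[0.8, 0.1], [0.1, 0.3]])
        post = update(pred, Observation(1, -0.5), UNIT)
        np.testing.assert_allclose(post.mean, pred.mean, atol=1e-12)

    def test_state_variance_strictly_contracts(self, rng):
        for _ in range(30):
            v = rng.uniform(0.2, 2.0)
            c = rng.uniform(-0.3, 0.3) * v
            pred = belief([rng.normal(), 1.0], [[v, c], [c, 0.5]])
            obs = Observation(int(rng.random() < 0.5), rng.normal())
            post = update(pred, obs, UNIT)
            assert post.cov[0, 0] < pred.cov[0, 0]

    def test_auxiliary_moves_only_through_coupling(self):
        obs = Observation(1, 1.0)
        decoupled = update(belief([0.0, 1.0], np.diag([1.0, 0.5])), obs, UNIT)
        assert decoupled.mean[1] == 1.0  # zero off-diagonal: no information flows
        coupled = update(belief([0.0, 1.0], [[1.0, 0.4], [0.4, 0.5]]), obs, UNIT)
        assert coupled.mean[1] != 1.0

    def test_iterated_update_finds_posterior_mode(self, rng):
        # Iterated Newton refinement must land on the grid/scalar-optimizer
        # mode of prior x likelihood (diagonal prior: 1-D problem).
        for _ in range(20):
            m = rng.normal(scale=0.8)
            v = rng.uniform(0.3, 2.0)
            obs = Observation(int(rng.random() < 0.5), rng.normal(scale=0.8))
            pred = belief([m, 1.0], np.diag([v, 0.5]))
            post = update(pred, obs, UNIT, iterate=True)

            def neg_log_post(x):
                return 0.5 * (x - m) ** 2 / v - log_observation_likelihood(
                    obs, x, UNIT
                )

            res = minimize_scalar(
                neg_log_post, bracket=(m - 3, m, m + 3), method="brent", options={"xtol": 1e-12}
            )
            assert post.mean[0] == pytest.approx(res.x, abs=1e-7)

    def test_single_step_mean_brackets_mode(self, rng):
        # The one-step update moves from the prediction toward the mode and
        # stays within a unit-wide bracket of it when the prediction is close.
        for _ in range(20):
            m = rng.normal(scale=0.5)
            obs = Observation(int(rng.random() < 0.5), m + rng.normal(scale=0.5))
            pred = belief([m, 1.0], np.diag([0.8, 0.5]))
            one_step = update(pred, obs, UNIT).mean[0]
            mode = update(pred, obs, UNIT, iterate=True).mean[0]
            if abs(m - mode) < 1.0:
                assert abs(one_step - mode) <= abs(m - mode) + 1e-12


class TestKalmanReduction:
    def test_matches_linear_kalman_with_binary_disabled(self, rng):
        """With the SCR channel off, the update must equal the exact Kalman
        update for the linear-Gaussian tonic channel (robust track is linear)."""
        params = ObservationParams(
            gamma=0.0, tonic_intercept=0.3, tonic_slope=0.7, tonic_noise_var=0.2
        )
        noise = StateNoiseParams(0.01, disturbance_walk_var=1e-3)
        model = robust_model(noise)
        C = np.array([params.tonic_slope, 0.0])
        F = np.array([[1.0, 1.0], [0.0, 1.0]])
        K_proc = model.process_cov

        mean = np.array([0.0, 0.0])
        cov = np.diag([1.0, 0.1])
        b = belief(mean, cov, "robust")
        for k in range(200):
            r = rng.normal(scale=1.0)
            obs = Observation(0, r)
            b_post = update(b, obs, params, binary_channel=False)
            # hand-coded Kalman
            S = C @ cov @ C + params.tonic_noise_var
            Kg = cov @ C / S
            mean_k = mean + Kg * (r - params.tonic_intercept - C @ mean)
            cov_k = cov - np.outer(Kg, C @ cov)
            np.testing.assert_allclose(b_post.mean, mean_k, atol=1e-10)
            np.testing.assert_allclose(b_post.cov, cov_k, atol=1e-10)
            u = 0.1 * np.sin(k / 10)
            b = predict(b_post, u, model)
            mean = F @ mean_k + np.array([u, 0.0])
            cov = F @ cov_k @ F.T + K_proc


class TestFilterSeries:
    def test_empty_sequence_returns_initial_belief_only(self):
        model = adaptive_model(StateNoiseParams(0.01, gain_walk_var=1e-4))
        init = belief([0.0, 1.0], np.diag([1.0, 0.1]))
        trace = filter_series([], [], model, UNIT, init)
        assert trace.predicted == [init]
        assert trace.updated == []

    def test_length_mismatch_rejected(self):
        model = adaptive_model(StateNoiseParams(0.01, gain_walk_var=1e-4))
        init = belief([0.0, 1.0], np.diag([1.0, 0.1]))
        with pytest.raises(ValueError):
            filter_series([Observation(0, 0.0)], [], model, UNIT, init)

    def test_single_step_is_update_then_predict(self):
        model = adaptive_model(StateNoiseParams(0.01, gain_walk_var=1e-4))
        init = belief([0.2, 0.9], np.diag([1.0, 0.1]))
        obs = Observation(1, 0.4)
        trace = filter_series([obs], [0.3], model, UNIT, init)
        direct = update(init, obs, UNIT)
        np.testing.assert_allclose(trace.updated[0].mean, direct.mean)
        np.testing.assert_allclose(trace.updated[0].cov, direct.cov)

    def test_covariances_stay_psd_over_long_run(self, rng):
        model = robust_model(StateNoiseParams(0.01, disturbance_walk_var=1e-3))
        b = belief([0.0, 0.0], np.diag([1.0, 0.1]), "robust")
        for _ in range(10_000):
            obs = Observation(int(rng.random() < 0.3), rng.normal())
            b = update(b, obs, UNIT)
            assert abs(b.cov[0, 1] - b.cov[1, 0]) < 1e-12
            assert np.linalg.eigvalsh(b.cov).min() >= -1e-10
            b = predict(b, 0.0, model)

    def test_adaptive_filter_beats_nominal_on_timevarying_data(self):
        """On data generated with a drifting gain, the augmented filter's
        state RMSE should beat the nominal filter's in a majority of seeds."""
        from arousalctl import Observation, sample_observation, step_timevarying

        params = ObservationParams(
            gamma=-1.0, tonic_intercept=0.0, tonic_slope=1.0, tonic_noise_var=0.1
        )
        noise = StateNoiseParams(0.005, gain_walk_var=2e-4)
        sched = make_stimulus_schedule(
            [("stress", 50, 0.08), ("relax", 50, 0.0)] * 3
        )
        model = adaptive_model(noise)
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            r = np.random.default_rng(np.random.SeedSequence((4242, seed)))
            # drifting-gain truth, clipped to the stable band so the
            # uncontrolled trajectory stays bounded
            x, rho = 0.0, 0.9
            states, observations = [], []
            for s in sched.values:
                states.append(x)
                observations.append(sample_observation(x, params, r))
                x, rho = step_timevarying(x, rho, float(s), 0.0, noise, r)
                rho = min(max(rho, 0.5), 1.0)
            states = np.array(states)
            controls = np.zeros(len(states))
            init = belief([0.0, 1.0], np.diag([1.0, 0.1]))
            trace = filter_series(observations, controls, model, params, init)
            x_aug = np.array([u.mean[0] for u in trace.updated])
            nom = filter_nominal(observations, controls, params, noise)
            rmse_aug = np.sqrt(np.mean((x_aug - states) ** 2))
            rmse_nom = np.sqrt(np.mean((nom.mean_post - states) ** 2))
            wins += rmse_aug < rmse_nom
        assert wins > n_seeds / 2


class TestNominalFilter:
    def test_equals_robust_filter_with_pinned_disturbance(self, rng):
        """Robust filter with a point-mass d-prior at 0 and zero walk variance
        must reduce exactly to the scalar nominal filter."""
        noise = StateNoiseParams(0.02, disturbance_walk_var=0.0)
        model = robust_model(noise)
        obs = [Observation(int(rng.random() < 0.4), rng.normal()) for _ in range(100)]
        controls = list(0.05 * np.sin(np.arange(100) / 7))
        init2 = belief([0.0, 0.0], np.diag([1.0, 0.0]), "robust")
        trace2 = filter_series(obs, controls, model, UNIT, init2)
        nom = filter_nominal(
            obs, controls, UNIT, noise, initial_mean=0.0, initial_var=1.0
        )
        x2 = np.array([u.mean[0] for u in trace2.updated])
        v2 = np.array([u.cov[0, 0] for u in trace2.updated])
        np.testing.assert_allclose(x2, nom.mean_post, atol=1e-10)
        np.testing.assert_allclose(v2, nom.var_post, atol=1e-10)

    def test_zero_information_leaves_mean_unchanged(self):
        noise = StateNoiseParams(0.02)
        obs = [Observation(1, 0.7), Observation(0, -0.2)]
        nom = filter_nominal(
            obs, [0.0, 0.0], UNIT, noise,
            initial_mean=0.4, binary_channel=False, tonic_channel=False,
        )
        np.testing.assert_allclose(nom.mean_post, [0.4, 0.4], atol=1e-14)

    def test_deterministic(self):
        noise = StateNoiseParams(0.02)
        obs = [Observation(1, 0.7), Observation(0, -0.2), Observation(0, 0.1)]
        a = filter_nominal(obs, [0.1, 0.0, -0.1], UNIT, noise)
        b = filter_nominal(obs, [0.1, 0.0, -0.1], UNIT, noise)
        np.testing.assert_array_equal(a.mean_post, b.mean_post)
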