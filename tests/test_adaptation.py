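"""The between-trial learning law and its decomposition."""

import dataclasses

import numpy as np
import pytest

import impedadapt as ia
from impedadapt.adaptation import (
    apply_rbf_update,
    cost,
    decompose_update,
    error_drive,
    gradient_update,
)
from impedadapt.config import FeedbackConfig, LearningConfig


@pytest.fixture()
def lc():
    return LearningConfig(error_weight=1.0, effort_weight=0.002, rate=2.0)


@pytest.fixture()
def gains():
    return FeedbackConfig(stretch_slope=30.0, shortening_slope=15.0)


class TestCost:
    def test_zero_trajectories_zero_cost(self, lc, gains):
        z = np.zeros((50, 6))
        assert cost(z, z, lc, gains, 0.001) == 0.0

    def test_effort_term_linear_in_activation(self, lc, gains, rng):
        s = np.zeros((50, 6))
        u = rng.uniform(0, 1, (50, 6))
        j1 = cost(s, u, lc, gains, 0.001)
        j3 = cost(s, 3 * u, lc, gains, 0.001)
        assert np.isclose(j3, 3 * j1)

    def test_matches_explicit_quadrature(self, lc, gains, rng):
        s = rng.normal(scale=0.005, size=(40, 6))
        u = rng.uniform(0, 1, (40, 6))
        dt = 0.001
        expected = 0.0
        for t in range(40):
            v = np.where(s[t] > 0, 30.0 * s[t], -15.0 * s[t])
            expected += 0.5 * lc.error_weight * float(v @ v) * dt
            expected += lc.effort_weight * float(u[t].sum()) * dt
        assert np.isclose(cost(s, u, lc, gains, dt), expected, rtol=1e-8)

    def test_length_mismatch_rejected(self, lc, gains):
        with pytest.raises(ValueError):
            cost(np.zeros((10, 6)), np.zeros((9, 6)), lc, gains, 0.001)


class TestGradientUpdate:
    def test_zero_error_pure_decay(self, lc, gains):
        w = np.array([0.5, 0.01, 0.0])
        phi = np.zeros((20, 6, 3))
        s = np.zeros((20, 6))
        w2, dec = gradient_update(w, phi, s, lc, gains, 0.001)
        assert np.allclose(w2, np.maximum(w - lc.decay, 0.0))
        assert np.all(dec.decay <= 0)
        assert np.allclose(dec.reciprocal, 0) and np.allclose(dec.coactivation, 0)

    def test_single_step_identity_basis(self, gains):
        lc0 = LearningConfig(rate=2.0, effort_weight=0.0)
        phi = np.eye(6)[None, :, :]
        s = np.array([[0.01, -0.01, 0, 0, 0.002, 0]])
        w0 = np.full(6, 0.5)
        w2, _ = gradient_update(w0, phi, s, lc0, gains, 1.0)
        assert np.allclose(w2 - w0, 2.0 * error_drive(s[0], gains))

    def test_update_equals_minus_gradient_of_cost(self, lc, gains, rng):
        # independent central-difference oracle on the absorbed-feedback
        # cost model J(w) = Q/2 sum ||v0 - Phi (w - w0)||^2 dt + R ||w||_1
        T, P = 5, 4
        phi = rng.uniform(0, 1, (T, 6, P))
        s = rng.normal(scale=0.01, size=(T, 6))
        w0 = rng.uniform(1.0, 2.0, P)
        dt = 0.01
        v0 = error_drive(s, gains)

        def J(w):
            err = 0.0
            for t in range(T):
                u_fb = v0[t] - phi[t] @ (w - w0)
                err += 0.5 * lc.error_weight * float(u_fb @ u_fb) * dt
            return err + lc.effort_weight * float(np.sum(w))

        grad = np.empty(P)
        h = 1e-6
        for j in range(P):
            dw = np.zeros(P)
            dw[j] = h
            grad[j] = (J(w0 + dw) - J(w0 - dw)) / (2 * h)
        lc_dt = dataclasses.replace(lc, decay=lc.rate * lc.effort_weight)
        w2, _ = gradient_update(w0, phi, s, lc_dt, gains, dt)
        update = w2 - w0
        expected = -lc.rate * grad
        assert np.allclose(update, expected, rtol=1e-4, atol=1e-10)

    def test_nonfinite_error_discards_trial(self, lc, gains):
        w = np.ones(3)
        phi = np.ones((5, 6, 3))
        s = np.full((5, 6), np.nan)
        with pytest.warns(UserWarning):
            w2, dec = gradient_update(w, phi, s, lc, gains, 0.001)
        assert np.array_equal(w2, w)
        assert np.allclose(dec.applied, 0.0)


class TestDecomposition:
    def test_three_terms_sum_to_applied_update(self, lc, gains, rng):
        T, P = 8, 5
        phi = rng.uniform(0, 1, (T, 6, P))
        s = rng.normal(scale=0.01, size=(T, 6))
        w0 = rng.uniform(0.0, 0.1, P)
        w2, dec = gradient_update(w0, phi, s, lc, gains, 0.001)
        assert np.allclose(dec.applied, w2 - w0, atol=1e-15)
        dec2 = decompose_update(w2 - w0, s, phi, lc, gains, 0.001)
        assert np.allclose(
            dec2.reciprocal + dec2.coactivation + dec2.decay, w2 - w0,
            atol=1e-15,
        )

    def test_stretch_only_error(self, lc, gains, rng):
        # with no shortening anywhere the full drive is a+ * s
        T, P = 6, 3
        phi = rng.uniform(0, 1, (T, 6, P))
        s = rng.uniform(0, 0.01, (T, 6))
        _, dec = gradient_update(np.ones(P), phi, s, lc, gains, 0.001)
        scale = lc.rate * lc.error_weight * 0.001
        total = scale * np.einsum("tmp,tm->p", phi, 30.0 * s)
        assert np.allclose(dec.reciprocal + dec.coactivation, total)

    def test_zero_error_zero_error_terms(self, lc, gains):
        _, dec = gradient_update(
            np.ones(3), np.ones((4, 6, 3)), np.zeros((4, 6)), lc, gains, 0.001
        )
        assert np.allclose(dec.reciprocal, 0) and np.allclose(dec.coactivation, 0)

    def test_decay_term_never_positive(self, lc, gains, rng):
        for _ in range(200):
            phi = rng.uniform(0, 1, (3, 6, 4))
            s = rng.normal(scale=0.02, size=(3, 6))
            w = rng.uniform(0, 0.05, 4)
            _, dec = gradient_update(w, phi, s, lc, gains, 0.001)
            assert np.all(dec.decay <= 1e-15)


class TestInvariants:
    def test_weights_never_negative_over_many_random_updates(self, gains, rng):
        lc = LearningConfig(rate=5.0, effort_weight=0.01)
        w = rng.uniform(0, 1, 5)
        for _ in range(10_000):
            phi = rng.uniform(0, 1, (2, 6, 5))
            s = rng.normal(scale=0.02, size=(2, 6))
            w, _ = gradient_update(w, phi, s, lc, gains, 0.01)
            assert np.all(w >= 0)

    def test_decay_regime_weight_norm_monotone(self, lc, gains):
        w = np.array([1.0, 0.3, 0.004, 0.0])
        norms = [np.linalg.norm(w)]
        for _ in range(50):
            w, _ = gradient_update(
                w, np.zeros((5, 6, 4)), np.zeros((5, 6)), lc, gains, 0.001
            )
            norms.append(np.linalg.norm(w))
        assert all(b <= a + 1e-15 for a, b in zip(norms, norms[1:]))
        assert norms[-1] < norms[0]

    def test_winner_take_all_smaller_parameter_dies_first(self, gains):
        # uniform decay with unequal error-driven increments: the weakly
        # supported parameter hits zero first
        lc = LearningConfig(rate=1.0, effort_weight=0.5)
        w = np.array([0.3, 0.3])
        phi = np.array([[[1.0, 0.1]] * 6])  # param 0 reinforced 10x more
        s = np.full((1, 6), 0.01)
        died = [None, None]
        for k in range(200):
            w, _ = gradient_update(w, phi, s, lc, gains, 1.0)
            for j in (0, 1):
                if died[j] is None and w[j] == 0.0:
                    died[j] = k
        assert died[1] is not None
        assert died[0] is None or died[0] > died[1]


class TestRBFEquivalence:
    def test_network_update_equals_generic_law(self, cfg, small_net, reach, rng):
        # the network update computed from the simulator's accumulators is
        # the generic linear-in-parameters law with Phi = kron(I, g^T)
        net = ia.RBFNetwork.from_dict(small_net.to_dict())
        net.W = rng.uniform(0, 0.5, net.W.shape)
        res = ia.simulate_trial(reach, net, ia.null_field(), cfg,
                                rng=rng, engine="python")
        W_before = net.W.copy()
        apply_rbf_update(net, res, cfg)
        # generic path on the flattened weights
        n = res.n_steps
        phi = np.stack([
            np.kron(np.eye(6), net.activations(
                np.concatenate([res.q[i], res.qd[i]]))[None, :])
            for i in range(n)
        ])
        w2, _ = gradient_update(
            W_before.reshape(-1), phi, res.s, cfg.learning, cfg.feedback,
            reach.dt,
        )
        assert np.allclose(net.W.reshape(-1), w2, rtol=1e-9, atol=1e-12)

    def test_noise_alone_builds_coactivation(self, cfg, small_net, rng):
        # pure stochastic deviation (no systematic error) strictly raises
        # the torque-balanced co-activation of the feedforward command
        from impedadapt.experiments import CENTER

        noisy = cfg.replace(
            simulation=dataclasses.replace(
                cfg.simulation, baseline_activation=0.5
            ),
            noise=dataclasses.replace(cfg.noise, cv=0.1),
        )
        plan = ia.reach_plan(CENTER, CENTER, 0.3, noisy)
        net = ia.RBFNetwork.from_dict(small_net.to_dict())
        x0 = np.concatenate([plan.q[0], plan.qd[0]])

        def coact(u):
            return float(np.sum(np.minimum(u[0::2], u[1::2])))

        before = coact(net.evaluate(x0))
        for _ in range(50):
            res = ia.simulate_trial(plan, net, ia.null_field(), noisy, rng=rng)
            apply_rbf_update(net, res, noisy)
        after = coact(net.evaluate(x0))
        assert after > before

    def test_zero_trials_leave_model_unchanged(self, cfg, small_net):
        net = ia.RBFNetwork.from_dict(small_net.to_dict())
        hist = ia.run_learning([], net, cfg, seed=0)
        assert len(hist.records) == 0
        assert np.array_equal(net.W, small_net.W)

    def test_aborted_trial_skips_update(self, cfg, small_net, reach, rng):
        tight = cfg.replace(
            simulation=dataclasses.replace(cfg.simulation, max_hand_speed=0.01)
        )
        net = ia.RBFNetwork.from_dict(small_net.to_dict())
        net.W += 0.3
        W0 = net.W.copy()
        res = ia.simulate_trial(reach, net, ia.null_field(), tight, rng=rng)
        assert res.aborted
        apply_rbf_update(net, res, tight)
        assert np.array_equal(net.W, W0)
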