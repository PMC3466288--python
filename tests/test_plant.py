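"""Arm mechanics: muscle geometry, tension law, dynamics, noise."""

import numpy as np
import pytest

import impedadapt as ia
from impedadapt.config import ArmParameters, MuscleGeometry, MuscleParameters
from impedadapt.plant import (
    ArmState,
    forward_dynamics,
    forward_kinematics,
    inertia_matrix,
    inverse_kinematics,
    jacobian,
    joint_torque,
    kinetic_energy,
    muscle_lengths,
    muscle_tension,
    signal_dependent_noise,
)


class TestMuscleGeometry:
    def test_reference_posture_gives_reference_lengths(self, cfg):
        st = ArmState(cfg.geometry.q_ref.copy(), np.zeros(2))
        l, ld = muscle_lengths(st, cfg.geometry)
        assert np.allclose(l, cfg.geometry.l0)
        assert np.allclose(ld, 0.0)

    def test_shoulder_flexion_shortens_its_flexor(self, cfg):
        # moment arm 0.04 m, +0.1 rad flexion -> 4 mm shortening
        q = cfg.geometry.q_ref + np.array([0.1, 0.0])
        l, _ = muscle_lengths(ArmState(q, np.zeros(2)), cfg.geometry)
        assert np.isclose(l[0] - cfg.geometry.l0[0], -0.004)
        # elbow muscles unaffected by pure shoulder rotation
        assert np.allclose(l[2:4], cfg.geometry.l0[2:4])

    def test_biarticular_length_velocity_is_minus_At_qd(self):
        geom = MuscleGeometry(
            moment_arms=np.array(
                [
                    [0.04, -0.04, 0.0, 0.0, 0.03, -0.03],
                    [0.0, 0.0, 0.025, -0.025, 0.025, -0.025],
                ]
            )
        )
        st = ArmState(geom.q_ref.copy(), np.array([1.0, 0.0]))
        _, ld = muscle_lengths(st, geom)
        assert np.isclose(ld[4], -0.03)

    def test_elbow_only_rotation_leaves_shoulder_muscles(self, cfg):
        qa = cfg.geometry.q_ref
        qb = qa + np.array([0.0, 0.2])
        la, _ = muscle_lengths(ArmState(qa, np.zeros(2)), cfg.geometry)
        lb, _ = muscle_lengths(ArmState(qb, np.zeros(2)), cfg.geometry)
        delta = lb - la
        assert np.allclose(delta[:2], 0.0)
        assert np.all(np.abs(delta[2:]) > 0)

    def test_non_finite_state_rejected(self):
        with pytest.raises(ValueError):
            ArmState(np.array([np.nan, 0.0]), np.zeros(2))


class TestMuscleTension:
    def test_silent_muscle_at_rest_produces_no_tension(self, cfg):
        T = muscle_tension(np.zeros(6), np.zeros(6), np.zeros(6), cfg.muscle)
        assert np.allclose(T, 0.0)

    def test_stretch_increases_tension(self, cfg):
        u = np.full(6, 0.2)
        T0 = muscle_tension(u, np.zeros(6), np.zeros(6), cfg.muscle)
        T1 = muscle_tension(u, np.full(6, 0.003), np.zeros(6), cfg.muscle)
        assert np.all(T1 > T0)

    def test_tension_never_negative(self, cfg, rng):
        for _ in range(100):
            u = rng.uniform(0, 2, 6)
            e = rng.uniform(-0.05, 0.05, 6)
            ed = rng.uniform(-0.5, 0.5, 6)
            assert np.all(muscle_tension(u, e, ed, cfg.muscle) >= 0)

    def test_torque_balanced_coactivation(self, cfg):
        # equal activation of an antagonist pair with matched moment arms
        # and T0 produces zero net torque, at any co-activation level
        A = cfg.geometry.moment_arms
        for c in (0.1, 0.5, 1.0):
            u = np.full(6, c)
            T = muscle_tension(u, np.zeros(6), np.zeros(6), cfg.muscle)
            assert np.allclose(A @ T, 0.0, atol=1e-9)

    def test_negative_activation_rejected(self, cfg):
        with pytest.raises(ValueError):
            muscle_tension(np.array([-0.1, 0, 0, 0, 0, 0]), np.zeros(6),
                           np.zeros(6), cfg.muscle)


class TestJointTorque:
    def test_zero_tension_zero_torque(self, cfg):
        assert np.allclose(joint_torque(np.zeros(6), cfg.geometry), 0.0)

    def test_antagonist_pair_cancels(self, cfg):
        T = np.array([10.0, 10.0, 0, 0, 0, 0])
        assert np.allclose(joint_torque(T, cfg.geometry), 0.0)

    def test_monoarticular_unit_tension(self, cfg):
        T = np.zeros(6)
        T[0] = 1.0
        tau = joint_torque(T, cfg.geometry)
        assert np.isclose(tau[0], 0.04)
        assert np.isclose(tau[1], 0.0)


class TestSignalDependentNoise:
    def test_zero_activation_exactly_zero(self):
        out = signal_dependent_noise(np.zeros(6), 0.1, 0)
        assert np.array_equal(out, np.zeros(6))

    def test_zero_coefficient_is_identity(self, rng):
        u = rng.uniform(0, 1, 6)
        assert np.array_equal(signal_dependent_noise(u, 0.0, rng), u)

    def test_noise_std_proportional_to_activation(self):
        rng = np.random.default_rng(7)
        u = np.ones((100_000, 1)) @ np.ones((1, 1))
        draws = np.array(
            [signal_dependent_noise(np.array([1.0]), 0.1, rng)[0]
             for _ in range(100_000)]
        )
        assert abs(np.std(draws) - 0.1) < 0.002


class TestForwardDynamics:
    def test_rest_stays_at_rest(self, cfg):
        st = ArmState(np.array([1.0, 1.5]), np.zeros(2))
        qdd = forward_dynamics(st, np.zeros(2), np.zeros(2), cfg.arm,
                               viscosity=np.zeros((2, 2)))
        assert np.allclose(qdd, 0.0)

    def test_massless_distal_link_reduces_to_single_link(self):
        arm = ArmParameters(m2=1e-9, I2=1e-9, lc2=1e-6)
        st = ArmState(np.array([0.5, 1.0]), np.zeros(2))
        tau = np.array([1.0, 0.0])
        qdd = forward_dynamics(st, tau, np.zeros(2), arm,
                               viscosity=np.zeros((2, 2)))
        I_total = arm.I1 + arm.m1 * arm.lc1**2
        assert np.isclose(qdd[0], tau[0] / I_total, rtol=1e-4)

    def test_passive_energy_conserved(self, cfg):
        # no torques, no viscosity, no field: kinetic energy constant to
        # integrator tolerance over 1 s of RK4 at 1 ms
        arm = cfg.arm
        y = np.array([0.8, 1.4, 1.0, -1.5])
        E0 = kinetic_energy(y[:2], y[2:], arm)

        def f(y):
            st = ArmState(y[:2], y[2:])
            qdd = forward_dynamics(st, np.zeros(2), np.zeros(2), arm,
                                   viscosity=np.zeros((2, 2)))
            return np.concatenate([y[2:], qdd])

        dt = 0.001
        for _ in range(1000):
            k1 = f(y)
            k2 = f(y + dt / 2 * k1)
            k3 = f(y + dt / 2 * k2)
            k4 = f(y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        E1 = kinetic_energy(y[:2], y[2:], arm)
        assert abs(E1 - E0) / E0 < 1e-4

    def test_dynamics_matches_lagrangian_derivation(self, cfg, rng):
        # independent derivation of the equations of motion via sympy
        sympy = pytest.importorskip("sympy")
        a = cfg.arm
        q1, q2, qd1, qd2 = sympy.symbols("q1 q2 qd1 qd2")
        t = sympy.symbols("t")
        f1, f2 = sympy.Function("f1")(t), sympy.Function("f2")(t)
        # kinetic energy of the two links
        x1 = a.lc1 * sympy.cos(f1)
        y1 = a.lc1 * sympy.sin(f1)
        x2 = a.l1 * sympy.cos(f1) + a.lc2 * sympy.cos(f1 + f2)
        y2 = a.l1 * sympy.sin(f1) + a.lc2 * sympy.sin(f1 + f2)
        v1sq = sympy.diff(x1, t) ** 2 + sympy.diff(y1, t) ** 2
        v2sq = sympy.diff(x2, t) ** 2 + sympy.diff(y2, t) ** 2
        L = (
            a.m1 * v1sq / 2 + a.m2 * v2sq / 2
            + a.I1 * sympy.diff(f1, t) ** 2 / 2
            + a.I2 * (sympy.diff(f1, t) + sympy.diff(f2, t)) ** 2 / 2
        )
        eqs = [
            sympy.diff(sympy.diff(L, sympy.diff(f, t)), t) - sympy.diff(L, f)
            for f in (f1, f2)
        ]
        qdd1, qdd2 = sympy.symbols("qdd1 qdd2")
        subs = {
            sympy.diff(f1, t, 2): qdd1, sympy.diff(f2, t, 2): qdd2,
            sympy.diff(f1, t): qd1, sympy.diff(f2, t): qd2,
            f1: q1, f2: q2,
        }
        eqs = [sympy.expand(e).subs(subs) for e in eqs]
        sol = sympy.solve(
            [sympy.Eq(eqs[0], sympy.Symbol("tau1")),
             sympy.Eq(eqs[1], sympy.Symbol("tau2"))],
            [qdd1, qdd2],
        )
        fsol = sympy.lambdify(
            (q1, q2, qd1, qd2, sympy.Symbol("tau1"), sympy.Symbol("tau2")),
            [sol[qdd1], sol[qdd2]],
        )
        for _ in range(100):
            qv = rng.uniform([0.2, 0.3], [1.5, 2.2])
            qdv = rng.uniform(-3, 3, 2)
            tau = rng.uniform(-5, 5, 2)
            ours = forward_dynamics(
                ArmState(qv, qdv), tau, np.zeros(2), a,
                viscosity=np.zeros((2, 2)),
            )
            ref = np.array(fsol(*qv, *qdv, *tau))
            assert np.allclose(ours, ref, rtol=1e-6, atol=1e-6)

    def test_singular_posture_with_force_rejected(self, cfg):
        st = ArmState(np.array([0.5, 0.0]), np.zeros(2))  # elbow extended
        with pytest.raises(ValueError):
            forward_dynamics(st, np.zeros(2), np.array([1.0, 0.0]), cfg.arm)


class TestKinematics:
    def test_inverse_forward_roundtrip(self, cfg, rng):
        for _ in range(50):
            q = rng.uniform([0.2, 0.3], [1.5, 2.2])
            p = forward_kinematics(q, cfg.arm)
            q2 = inverse_kinematics(p, cfg.arm)
            assert np.allclose(forward_kinematics(q2, cfg.arm), p, atol=1e-10)

    def test_unreachable_point_rejected(self, cfg):
        with pytest.raises(ValueError):
            inverse_kinematics(np.array([1.0, 1.0]), cfg.arm)

    def test_jacobian_matches_finite_differences(self, cfg):
        q = np.array([0.9, 1.3])
        J = jacobian(q, cfg.arm)
        h = 1e-7
        for j in range(2):
            dq = np.zeros(2)
            dq[j] = h
            col = (forward_kinematics(q + dq, cfg.arm)
                   - forward_kinematics(q - dq, cfg.arm)) / (2 * h)
            assert np.allclose(J[:, j], col, atol=1e-6)
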