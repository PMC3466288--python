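"""Planar two-joint six-muscle arm.

Rigid-body dynamics of a two-link arm moving in the horizontal plane (no
gravity), actuated by six pull-only muscles with constant moment arms and
activation-dependent visco-elasticity, perturbed by signal-dependent motor
noise.  The shoulder sits at the origin, x points to the subject's right,
y away from the body; joint angles are counter-clockwise positive.

This module is the readable reference implementation of the per-time-step
loop; :mod:`impedadapt._core` repeats it in compiled form for long protocols
and the two are held together by an equivalence test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ArmParameters, Config, MuscleGeometry, MuscleParameters

__all__ = [
    "ArmState",
    "MusclePattern",
    "forward_kinematics",
    "jacobian",
    "inverse_kinematics",
    "inertia_matrix",
    "coriolis_matrix",
    "muscle_lengths",
    "muscle_tension",
    "joint_torque",
    "signal_dependent_noise",
    "forward_dynamics",
    "kinetic_energy",
    "step",
]


@dataclass
class ArmState:
    """Joint angles (rad), velocities (rad/s) and time (s)."""

    q: np.ndarray
    qdot: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.qdot = np.asarray(self.qdot, dtype=float)
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.qdot))):
            raise ValueError("arm state must be finite")

    def hand(self, arm: ArmParameters) -> np.ndarray:
        return forward_kinematics(self.q, arm)

    def hand_velocity(self, arm: ArmParameters) -> np.ndarray:
        return jacobian(self.q, arm) @ self.qdot


@dataclass
class MusclePattern:
    """Activations with the tensions and visco-elasticity they produce."""

    u: np.ndarray
    tensions: np.ndarray
    stiffness: np.ndarray = field(default=None)
    viscosity: np.ndarray = field(default=None)


# ---------------------------------------------------------------------------
# kinematics


def forward_kinematics(q, arm: ArmParameters) -> np.ndarray:
    """Hand position (m) for joint angles ``q``."""
    q1, q2 = q
    return np.array(
        [
            arm.l1 * np.cos(q1) + arm.l2 * np.cos(q1 + q2),
            arm.l1 * np.sin(q1) + arm.l2 * np.sin(q1 + q2),
        ]
    )


def jacobian(q, arm: ArmParameters) -> np.ndarray:
    """Hand Jacobian d(hand)/d(q), 2x2."""
    q1, q2 = q
    s1, c1 = np.sin(q1), np.cos(q1)
    s12, c12 = np.sin(q1 + q2), np.cos(q1 + q2)
    return np.array(
        [
            [-arm.l1 * s1 - arm.l2 * s12, -arm.l2 * s12],
            [arm.l1 * c1 + arm.l2 * c12, arm.l2 * c12],
        ]
    )


def inverse_kinematics(hand, arm: ArmParameters) -> np.ndarray:
    """Joint angles reaching ``hand``, elbow-positive branch.

    Raises ``ValueError`` for points outside the reachable annulus.
    """
    x, y = hand
    r2 = x * x + y * y
    c2 = (r2 - arm.l1**2 - arm.l2**2) / (2 * arm.l1 * arm.l2)
    if not -1.0 <= c2 <= 1.0:
        raise ValueError(f"hand position {hand!r} outside the reachable workspace")
    q2 = np.arccos(c2)
    q1 = np.arctan2(y, x) - np.arctan2(arm.l2 * np.sin(q2), arm.l1 + arm.l2 * c2)
    return np.array([q1, q2])


# ---------------------------------------------------------------------------
# rigid-body dynamics


def inertia_matrix(q, arm: ArmParameters) -> np.ndarray:
    q2 = q[1]
    a = arm.I1 + arm.I2 + arm.m1 * arm.lc1**2 + arm.m2 * (
        arm.l1**2 + arm.lc2**2
    )
    b = arm.m2 * arm.l1 * arm.lc2
    d = arm.I2 + arm.m2 * arm.lc2**2
    c2 = np.cos(q2)
    return np.array([[a + 2 * b * c2, d + b * c2], [d + b * c2, d]])


def coriolis_matrix(q, qdot, arm: ArmParameters) -> np.ndarray:
    b = arm.m2 * arm.l1 * arm.lc2
    s2 = np.sin(q[1])
    h = b * s2
    return np.array(
        [[-h * qdot[1], -h * (qdot[0] + qdot[1])], [h * qdot[0], 0.0]]
    )


def kinetic_energy(q, qdot, arm: ArmParameters) -> float:
    return 0.5 * float(qdot @ inertia_matrix(q, arm) @ qdot)


def forward_dynamics(
    state: ArmState,
    tau: np.ndarray,
    F_ext: np.ndarray,
    arm: ArmParameters,
    *,
    viscosity: np.ndarray | None = None,
) -> np.ndarray:
    """Joint accelerations for joint torques ``tau`` and endpoint force ``F_ext``.

    ``qdd = M(q)^-1 (tau + J(q)^T F_ext - C(q, qd) qd - B qd)``.  The elbow
    close to full extension makes the hand Jacobian singular; dynamics remain
    well defined but a diagnostic is raised when an external endpoint force is
    applied there.
    """
    q, qd = state.q, state.qdot
    B = arm.viscosity if viscosity is None else viscosity
    F_ext = np.asarray(F_ext, dtype=float)
    J = jacobian(q, arm)
    if np.any(F_ext != 0.0) and abs(np.linalg.det(J)) < 1e-8:
        raise ValueError("endpoint force at a singular (fully extended) posture")
    M = inertia_matrix(q, arm)
    C = coriolis_matrix(q, qd, arm)
    rhs = tau + J.T @ F_ext - C @ qd - B @ qd
    return np.linalg.solve(M, rhs)


# ---------------------------------------------------------------------------
# muscle apparatus


def muscle_lengths(state: ArmState, geom: MuscleGeometry):
    """Muscle lengths and length velocities under the linearized geometry.

    ``l = l0 - A.T (q - q_ref)``; ``ldot = -A.T qdot``.  Flexion of a joint
    shortens its flexors (positive moment arm).
    """
    A = geom.moment_arms
    l = geom.l0 - A.T @ (state.q - geom.q_ref)
    ldot = -A.T @ state.qdot
    return l, ldot


def muscle_tension(
    u: np.ndarray,
    stretch: np.ndarray,
    stretch_rate: np.ndarray,
    muscle: MuscleParameters,
) -> np.ndarray:
    """Tension of each muscle (N); never negative (muscles only pull).

    ``T = max(0, T0 u + k(u) stretch + b(u) stretch_rate)`` with affine
    activation-dependent stiffness ``k`` and viscosity ``b``; ``stretch`` is
    the muscle length relative to its reference-trajectory length.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("muscle activations must be non-negative")
    T = (
        muscle.T0 * u
        + muscle.stiffness(u) * stretch
        + muscle.damping(u) * stretch_rate
    )
    return np.maximum(T, 0.0)


def joint_torque(T: np.ndarray, geom: MuscleGeometry) -> np.ndarray:
    """Joint torques (N m) produced by muscle tensions: ``tau = A T``."""
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError("muscle tensions must be non-negative")
    return geom.moment_arms @ T


def signal_dependent_noise(
    u: np.ndarray, cv: float, rng: np.random.Generator | int
) -> np.ndarray:
    """One multiplicative-scaling noise draw per muscle.

    Additive zero-mean Gaussian noise with standard deviation ``cv * u_i``,
    rectified at zero.  Within full trial simulations the same law is applied
    through a low-pass filtered (Ornstein–Uhlenbeck) process; this function is
    the single-draw primitive.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("activations must be non-negative")
    return np.maximum(u + cv * u * rng.standard_normal(u.shape), 0.0)


# ---------------------------------------------------------------------------
# one integration step (reference implementation)


def _plant_qdd(q, qd, u, l_r, l_rdot, field_force, cfg: Config):
    """Acceleration of the full muscle-driven plant at one evaluation point."""
    st = ArmState(q, qd)
    l, ld = muscle_lengths(st, cfg.geometry)
    T = muscle_tension(u, l - l_r, ld - l_rdot, cfg.muscle)
    tau = joint_torque(T, cfg.geometry)
    p = forward_kinematics(q, cfg.arm)
    v = jacobian(q, cfg.arm) @ qd
    F = field_force(p, v)
    M = inertia_matrix(q, cfg.arm)
    C = coriolis_matrix(q, qd, cfg.arm)
    rhs = tau + jacobian(q, cfg.arm).T @ F - C @ qd - cfg.arm.viscosity @ qd
    return np.linalg.solve(M, rhs), T, F


def step(
    state: ArmState,
    u: np.ndarray,
    field_force,
    cfg: Config,
    dt: float | None = None,
    reference=None,
):
    """Advance the plant by one RK4 step under constant command ``u``.

    ``field_force(p, v)`` maps hand position/velocity to the environmental
    endpoint force.  ``reference`` maps time to ``(l_r, l_rdot)``; when
    omitted the reference is frozen at the current muscle lengths (pure
    holding).  Returns the next state plus a log row dict.
    """
    if dt is None:
        dt = cfg.simulation.dt
    if dt <= 0:
        raise ValueError("dt must be positive")
    u = np.maximum(np.asarray(u, dtype=float), 0.0)
    t0 = state.time
    if reference is None:
        l_now, ld_now = muscle_lengths(state, cfg.geometry)
        reference = lambda t: (l_now, np.zeros_like(ld_now))  # noqa: E731

    def f(t, y):
        q, qd = y[:2], y[2:]
        l_r, l_rd = reference(t)
        qdd, _, _ = _plant_qdd(q, qd, u, l_r, l_rd, field_force, cfg)
        return np.concatenate([qd, qdd])

    y0 = np.concatenate([state.q, state.qdot])
    k1 = f(t0, y0)
    k2 = f(t0 + dt / 2, y0 + dt / 2 * k1)
    k3 = f(t0 + dt / 2, y0 + dt / 2 * k2)
    k4 = f(t0 + dt, y0 + dt * k3)
    y1 = y0 + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    nxt = ArmState(y1[:2], y1[2:], t0 + dt)

    l, ld = muscle_lengths(state, cfg.geometry)
    l_r, l_rd = reference(t0)
    _, T, F = _plant_qdd(state.q, state.qdot, u, l_r, l_rd, field_force, cfg)
    hand = forward_kinematics(state.q, cfg.arm)
    speed = float(np.linalg.norm(jacobian(nxt.q, cfg.arm) @ nxt.qdot))
    log = {
        "t": t0,
        "q": state.q.copy(),
        "qdot": state.qdot.copy(),
        "hand": hand,
        "l": l,
        "ldot": ld,
        "u": u,
        "T": T,
        "F_ext": F,
        "diverged": speed > cfg.simulation.max_hand_speed,
    }
    return nxt, log
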