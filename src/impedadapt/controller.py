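"""Motor command composition: reference plans, delayed V-shaped feedback.

The motor command for the six muscles is the sum of a learned feedforward
command and a delayed feedback command.  Feedback is driven by the *sliding
error* — the muscle-length error plus a velocity-weighted term, read out one
neural delay in the past — through a V-shaped function: zero at zero error,
linearly increasing for both stretch and shortening, with a steeper slope on
the stretch side.  The V-shape activates both muscles of an antagonist pair
whenever the hand is pushed off its reference path, so feedback responses
express co-activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import Config, FeedbackConfig
from .plant import forward_kinematics, inverse_kinematics, jacobian

__all__ = [
    "VShapeGains",
    "FeedbackError",
    "ReferencePlan",
    "minimum_jerk",
    "reach_plan",
    "circle_plan",
    "mean_trajectory_plan",
    "reference_muscle_lengths",
    "sliding_error",
    "vshape_feedback",
    "compose_command",
]

# The V-shape gains live in the feedback section of the configuration.
VShapeGains = FeedbackConfig


@dataclass
class FeedbackError:
    """Per-muscle feedback error with its stretch/shortening split."""

    e: np.ndarray
    edot: np.ndarray
    eps: np.ndarray
    delay: float

    @property
    def eps_plus(self) -> np.ndarray:
        """Positive (stretch) part; ``eps = eps_plus + eps_minus``."""
        return np.maximum(self.eps, 0.0)

    @property
    def eps_minus(self) -> np.ndarray:
        """Negative (shortening) part."""
        return np.minimum(self.eps, 0.0)


# ---------------------------------------------------------------------------
# reference trajectories


def minimum_jerk(start, goal, duration: float, t):
    """Minimum-jerk point-to-point hand trajectory.

    Fifth-order polynomial with zero velocity and acceleration at both ends;
    peak speed ``1.875 * distance / duration`` at mid-movement.  ``t`` may be
    scalar or array but must lie within ``[0, duration]``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > duration):
        raise ValueError("t must lie within [0, duration]")
    start = np.asarray(start, dtype=float)
    goal = np.asarray(goal, dtype=float)
    tau = t / duration
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    sd = (30 * tau**2 - 60 * tau**3 + 30 * tau**4) / duration
    d = goal - start
    pos = start + np.multiply.outer(s, d)
    vel = np.multiply.outer(sd, d)
    return pos, vel


@dataclass
class ReferencePlan:
    """A reference movement sampled on the simulation half-grid.

    Arrays are sampled at ``t = 0, dt/2, dt, ...`` (``2 n + 1`` points for an
    ``n``-step trial) so the RK4 stages of the integrator can read the
    reference exactly.  ``l_r``/``l_rdot`` are the reference muscle lengths
    and their rates; ``hand``/``q`` keep the planned hand and joint paths for
    metrics and plotting.
    """

    kind: str
    duration: float
    dt: float
    start: np.ndarray
    goal: np.ndarray
    hand: np.ndarray
    q: np.ndarray
    qd: np.ndarray
    l_r: np.ndarray
    l_rdot: np.ndarray

    @property
    def n_steps(self) -> int:
        return (self.l_r.shape[0] - 1) // 2

    def times(self) -> np.ndarray:
        return np.arange(self.l_r.shape[0]) * (self.dt / 2)


def _plan_from_hand(kind, start, goal, duration, hand, vel, dt, cfg: Config):
    q = np.empty((hand.shape[0], 2))
    qd = np.empty_like(q)
    for i in range(hand.shape[0]):
        q[i] = inverse_kinematics(hand[i], cfg.arm)
        qd[i] = np.linalg.solve(jacobian(q[i], cfg.arm), vel[i])
    A = cfg.geometry.moment_arms
    l_r = cfg.geometry.l0 - (q - cfg.geometry.q_ref) @ A
    l_rdot = -qd @ A
    return ReferencePlan(
        kind, duration, dt, np.asarray(start, float), np.asarray(goal, float),
        hand, q, qd, l_r, l_rdot,
    )


def reach_plan(
    start, goal, duration: float, cfg: Config, dt: float | None = None,
    hold: float = 0.0,
) -> ReferencePlan:
    """Minimum-jerk point-to-point plan, optionally held at the goal.

    ``hold`` extends the sampled plan beyond ``duration`` with the hand at
    rest on the goal, so a trial can settle.
    """
    dt = cfg.simulation.dt if dt is None else dt
    n = int(round((duration + hold) / dt))
    t = np.arange(2 * n + 1) * (dt / 2)
    t_mj = np.minimum(t, duration)
    pos, vel = minimum_jerk(start, goal, duration, t_mj)
    vel[t > duration] = 0.0
    return _plan_from_hand("point-to-point", start, goal, duration + hold, pos, vel, dt, cfg)


def circle_plan(
    center, radius: float, duration: float, cfg: Config,
    dt: float | None = None, start_angle: float = 0.0, ccw: bool = True,
) -> ReferencePlan:
    """One full constant-speed circular lap (counter-clockwise by default).

    Hand speed is ``2 pi radius / duration`` everywhere; the path closes on
    itself.  Rejected if any point of the circle leaves the workspace.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    dt = cfg.simulation.dt if dt is None else dt
    n = int(round(duration / dt))
    t = np.arange(2 * n + 1) * (dt / 2)
    omega = (1.0 if ccw else -1.0) * 2 * np.pi / duration
    phi = start_angle + omega * t
    center = np.asarray(center, dtype=float)
    pos = center + radius * np.stack([np.cos(phi), np.sin(phi)], axis=1)
    vel = radius * omega * np.stack([-np.sin(phi), np.cos(phi)], axis=1)
    start = pos[0].copy()
    return _plan_from_hand("circle", start, start, duration, pos, vel, dt, cfg)


def mean_trajectory_plan(
    template: ReferencePlan, l_r_history, l_rdot_history
) -> ReferencePlan:
    """Empirical-mean reference: average the stored muscle-length paths.

    Used for movements in the divergent field, where the motion error is
    taken relative to the mean of recent successful trials rather than an
    idealized minimum-jerk path.  ``template`` supplies timing and geometry.
    """
    l_r = np.mean(np.stack(l_r_history), axis=0)
    l_rdot = np.mean(np.stack(l_rdot_history), axis=0)
    return ReferencePlan(
        "empirical-mean", template.duration, template.dt, template.start,
        template.goal, template.hand, template.q, template.qd, l_r, l_rdot,
    )


def reference_muscle_lengths(plan: ReferencePlan, t: float):
    """Reference muscle lengths and rates at time ``t`` (half-grid lookup)."""
    if t < 0 or t > plan.duration + plan.dt:
        raise ValueError("t outside the plan's time span")
    i = min(int(round(2 * t / plan.dt)), plan.l_r.shape[0] - 1)
    return plan.l_r[i], plan.l_rdot[i]


# ---------------------------------------------------------------------------
# feedback pathway


def sliding_error(
    e_history: np.ndarray,
    edot_history: np.ndarray,
    kappa: float,
    delay: float,
    dt: float,
    i: int,
) -> np.ndarray:
    """Delayed sliding error at step ``i``.

    ``eps(t) = e(t - delay) + kappa * edot(t - delay)``; before one delay has
    elapsed no afferent information is available and the error is zero.
    """
    e_history = np.asarray(e_history)
    if e_history.size == 0:
        raise ValueError("empty error history")
    d = int(round(delay / dt))
    if i < d:
        return np.zeros(e_history.shape[1])
    return e_history[i - d] + kappa * np.asarray(edot_history)[i - d]


def vshape_feedback(eps: np.ndarray, gains: VShapeGains) -> np.ndarray:
    """V-shaped feedback activation: non-negative, zero only at zero error.

    ``u_fb = stretch_slope * eps+ - shortening_slope * eps-`` — both a
    stretched muscle and its shortening antagonist are activated, the former
    more strongly.
    """
    eps = np.asarray(eps, dtype=float)
    return (
        gains.stretch_slope * np.maximum(eps, 0.0)
        - gains.shortening_slope * np.minimum(eps, 0.0)
    )


def compose_command(u_ff: np.ndarray, u_fb: np.ndarray) -> np.ndarray:
    """Total motor command: rectified feedforward plus feedback."""
    return np.maximum(np.asarray(u_ff, dtype=float), 0.0) + np.asarray(
        u_fb, dtype=float
    )
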