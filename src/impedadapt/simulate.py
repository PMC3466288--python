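"""Single-trial simulation: the per-time-step loop of the whole model.

At every step the controller reads the reference muscle lengths, evaluates
the feedforward network at the current joint state, computes the delayed
sliding error and the V-shaped feedback, adds signal-dependent motor noise,
converts activations to visco-elastic muscle tensions and joint torques,
applies the environment force and integrates the rigid-body dynamics one RK4
step.  The undelayed sliding error is accumulated against the neuron
activations for the between-trial learning update.

Two engines produce identical trajectories: a readable pure-Python loop
(``engine="python"``) built from :mod:`impedadapt.plant` and
:mod:`impedadapt.controller`, and the numba-compiled loop in
:mod:`impedadapt._core` (default) used by the experiment protocols.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import controller as ctl
from . import plant
from ._core import sim_trial_core
from .config import Config
from .fields import _CURL, ForceFieldSpec, vfk_curl_gain
from .rbf import RBFNetwork

__all__ = ["TrialResult", "simulate_trial"]


@dataclass
class TrialResult:
    """Per-step log of one simulated trial."""

    t: np.ndarray            # (n+1,) step-grid times (s)
    q: np.ndarray            # (n+1, 2) joint angles
    qd: np.ndarray           # (n+1, 2) joint velocities
    hand: np.ndarray         # (n+1, 2) hand path (m)
    hand_vel: np.ndarray     # (n+1, 2) hand velocity (m/s)
    u_ff: np.ndarray         # (n, 6) feedforward commands
    u_fb: np.ndarray         # (n, 6) feedback commands
    u: np.ndarray            # (n, 6) total (noisy) commands
    tensions: np.ndarray     # (n, 6) muscle tensions (N)
    e: np.ndarray            # (n, 6) muscle length errors (m)
    s: np.ndarray            # (n, 6) undelayed sliding errors (m)
    F_ext: np.ndarray        # (n, 2) environment force (N)
    Gs: np.ndarray           # (6, N) sum_t outer(s, g) dt  (signed drive)
    Gabs: np.ndarray         # (6, N) sum_t outer(|s|, g) dt
    aborted: bool
    plan: ctl.ReferencePlan
    field: ForceFieldSpec
    meta: dict = dc_field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return self.u.shape[0]

    def lateral_deviation(self) -> np.ndarray:
        """Signed deviation from the straight start-goal line (m).

        Positive to the left of the start->goal direction.  Meaningful for
        point-to-point plans.
        """
        axis = self.plan.goal - self.plan.start
        nrm = np.linalg.norm(axis)
        if nrm < 1e-12:
            raise ValueError("degenerate plan: start equals goal")
        n_hat = axis / nrm
        l_hat = np.array([-n_hat[1], n_hat[0]])
        return (self.hand - self.plan.start) @ l_hat

    def terminal_error(self) -> float:
        return float(np.linalg.norm(self.hand[-1] - self.plan.goal))


def _field_core_params(spec: ForceFieldSpec):
    """Map a field spec to the compiled core's (ftype, FB, dfp) triple."""
    FB = np.zeros((2, 2))
    dfp = np.zeros(8)
    if spec.variant == "NF":
        return 0, FB, dfp
    if spec.variant == "VF":
        return 0, np.asarray(spec.matrix, dtype=float), dfp
    if spec.variant == "VFK":
        b = vfk_curl_gain(spec.direction, spec.k, spec.gain)
        return 0, b * _CURL, dfp
    dfp = np.array(
        [
            spec.gain,
            spec.start[0], spec.start[1],
            spec.goal[0], spec.goal[1],
            spec.barrier_threshold,
            spec.barrier_damping,
            spec.endzone_diameter / 2,
        ]
    )
    return 1, FB, dfp


def simulate_trial(
    plan: ctl.ReferencePlan,
    net: RBFNetwork,
    field: ForceFieldSpec,
    cfg: Config,
    rng: np.random.Generator | None = None,
    noise: bool = True,
    engine: str = "numba",
    error_plan: ctl.ReferencePlan | None = None,
) -> TrialResult:
    """Simulate one trial of ``plan`` in ``field`` with network ``net``.

    The arm starts on the plan's initial state (position and velocity).
    ``rng`` feeds the signal-dependent noise; with ``noise=False`` the run
    is fully deterministic.  ``error_plan``, when given, supplies the
    reference for the motion-error signal (feedback and learning) while
    ``plan`` keeps defining the mechanical muscle equilibrium — used for
    unstable tasks where the error is taken relative to the mean of recent
    trials rather than an idealized path.
    """
    err = error_plan if error_plan is not None else plan
    n = plan.n_steps
    dt = plan.dt
    fb = cfg.feedback
    d_steps = int(round(fb.delay / dt))
    alpha = float(np.exp(-2 * np.pi * cfg.noise.cutoff_hz * dt))
    if noise:
        if rng is None:
            raise ValueError("noise=True requires an rng")
        Z = rng.standard_normal((n, 6))
    else:
        Z = np.zeros((n, 6))

    if engine == "numba":
        ftype, FB, dfp = _field_core_params(field)
        (Q, QD, HAND, UFF, UFB, U, TT, E, ED, SARR, FX, Gs, Gabs,
         aborted, n_filled) = sim_trial_core(
            dt, n,
            plan.q[0].copy(), plan.qd[0].copy(),
            plan.l_r, plan.l_rdot,
            err.l_r, err.l_rdot,
            cfg.arm.l1, cfg.arm.l2, cfg.arm.m1, cfg.arm.m2,
            cfg.arm.lc1, cfg.arm.lc2, cfg.arm.I1, cfg.arm.I2,
            cfg.arm.viscosity,
            cfg.geometry.moment_arms, cfg.geometry.l0, cfg.geometry.q_ref,
            cfg.muscle.T0, cfg.muscle.k0, cfg.muscle.k1,
            cfg.muscle.b0, cfg.muscle.b1,
            fb.stretch_slope, fb.shortening_slope, fb.kappa, d_steps,
            cfg.simulation.baseline_activation,
            net.centers, net.widths, net.W, net.x_mean, net.x_scale,
            ftype, FB, dfp,
            cfg.noise.cv, alpha, Z, 1 if noise else 0,
            cfg.simulation.max_hand_speed,
        )
        m = n_filled
    elif engine == "python":
        (Q, QD, HAND, UFF, UFB, U, TT, E, ED, SARR, FX, Gs, Gabs,
         aborted, m) = _python_engine(
            plan, net, field, cfg, d_steps, alpha, Z, noise, err
        )
    else:
        raise ValueError(f"unknown engine {engine!r}")

    hv = np.empty_like(HAND)
    for i in range(m + 1):
        hv[i] = plant.jacobian(Q[i], cfg.arm) @ QD[i]
    hv[m + 1:] = 0.0
    t = np.arange(n + 1) * dt
    res = TrialResult(
        t=t, q=Q, qd=QD, hand=HAND, hand_vel=hv,
        u_ff=UFF, u_fb=UFB, u=U, tensions=TT, e=E, s=SARR, F_ext=FX,
        Gs=Gs, Gabs=Gabs, aborted=bool(aborted), plan=plan, field=field,
        meta={"field": field.describe(), "n_filled": int(m)},
    )
    if aborted:
        res.hand[m + 1:] = res.hand[m]
        res.q[m + 1:] = res.q[m]
        res.qd[m + 1:] = 0.0
    return res


def _python_engine(plan, net, field, cfg, d_steps, alpha, Z, noise, err=None):
    """Readable per-step loop; mirrors the compiled core operation by
    operation."""
    if err is None:
        err = plan
    n = plan.n_steps
    dt = plan.dt
    fb = cfg.feedback
    N = net.n_neurons
    Q = np.empty((n + 1, 2))
    QD = np.empty((n + 1, 2))
    HAND = np.empty((n + 1, 2))
    UFF = np.zeros((n, 6))
    UFB = np.zeros((n, 6))
    U = np.zeros((n, 6))
    TT = np.zeros((n, 6))
    E = np.zeros((n, 6))
    ED = np.zeros((n, 6))
    SARR = np.zeros((n, 6))
    FX = np.zeros((n, 2))
    Gs = np.zeros((6, N))
    Gabs = np.zeros((6, N))
    beta = np.sqrt(1 - alpha**2)
    nstate = np.zeros(6)
    state = plant.ArmState(plan.q[0].copy(), plan.qd[0].copy(), 0.0)
    Q[0], QD[0] = state.q, state.qdot
    HAND[0] = state.hand(cfg.arm)
    aborted = False
    m = 0

    def reference(t):
        return ctl.reference_muscle_lengths(plan, t)

    for i in range(n):
        l, ld = plant.muscle_lengths(state, cfg.geometry)
        E[i] = l - err.l_r[2 * i]
        ED[i] = ld - err.l_rdot[2 * i]
        SARR[i] = E[i] + fb.kappa * ED[i]
        eps = ctl.sliding_error(E[: i + 1], ED[: i + 1], fb.kappa, fb.delay, dt, i)
        UFB[i] = ctl.vshape_feedback(eps, fb)
        x = np.concatenate([state.q, state.qdot])
        g = net.activations(x)
        UFF[i] = net.evaluate(x)
        Gs[:, :] += np.outer(SARR[i], g) * dt
        Gabs[:, :] += np.outer(np.abs(SARR[i]), g) * dt
        cmd = ctl.compose_command(
            cfg.simulation.baseline_activation + UFF[i], UFB[i]
        )
        if noise:
            nstate = alpha * nstate + beta * Z[i]
            cmd = np.maximum(cmd * (1 + cfg.noise.cv * nstate), 0.0)
        U[i] = cmd
        state, log = plant.step(
            state, cmd, field.force, cfg, dt=dt, reference=reference
        )
        TT[i] = log["T"]
        FX[i] = log["F_ext"]
        Q[i + 1], QD[i + 1] = state.q, state.qdot
        HAND[i + 1] = state.hand(cfg.arm)
        m = i + 1
        if log["diverged"]:
            aborted = True
            break
    return Q, QD, HAND, UFF, UFB, U, TT, E, ED, SARR, FX, Gs, Gabs, aborted, m
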