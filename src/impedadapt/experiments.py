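"""Protocol drivers for the three simulated adaptation experiments.

* movement generalization: learn a velocity-dependent field either directly
  on a 10 cm-radius circle or on reaching movements in eight directions,
  then probe circles in the field and after its removal (axis-ratio metric);
* field granularity: reaching in 16 directions against direction-variant
  curl fields VF1/VF2/VF4 (velocity-correlation learning curves);
* impedance learning: point-to-point movements in two directions 35 degrees
  apart inside a divergent, laterally unstable field (endpoint stiffness
  ellipses before/after learning).

Each driver takes a master seed, draws all randomness from streams spawned
off it, and returns a plain results dictionary of metrics, logs and the
trained network.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field as dc_field

import numpy as np

from .adaptation import LearningHistory, apply_rbf_update
from .config import Config, default_config
from .controller import (
    ReferencePlan,
    circle_plan,
    mean_trajectory_plan,
    reach_plan,
)
from .fields import ForceFieldSpec, df_field, null_field, vf_field, vfk_field
from .metrics import (
    StiffnessEllipse,
    axis_ratio,
    endpoint_stiffness,
    smooth_curve,
    velocity_correlation,
)
from .rbf import RBFNetwork, select_network
from .simulate import simulate_trial

__all__ = [
    "Protocol",
    "CENTER",
    "DF_START",
    "df_goals",
    "states_from_plans",
    "network_for_plans",
    "run_conditt",
    "run_thoroughman",
    "run_kadiallah",
    "experiment_state_sets",
]

# workspace layout (m, shoulder at the origin, y away from the body)
CENTER = np.array([0.0, 0.45])       # centre point of the reaching workspace
REACH_LENGTH = 0.12
REACH_DURATION = 0.3
REACH_HOLD = 0.1
CIRCLE_RADIUS = 0.10
CIRCLE_DURATION = 0.3
DF_START = np.array([-0.09, 0.30])   # start of the unstable movements
DF_LENGTH = 0.25
DF_DURATION = 0.6
DF_HOLD = 0.15
DF_BEARINGS = (np.deg2rad(45.0), np.deg2rad(10.0))   # 35 degrees apart


@dataclass
class Protocol:
    """Descriptive record of one protocol run (goes into the manifest)."""

    name: str
    targets: list
    movement_length: float
    duration: float
    trial_counts: dict
    field: dict
    seed: int
    extra: dict = dc_field(default_factory=dict)


def df_goals() -> tuple[np.ndarray, np.ndarray]:
    """Goals of the two unstable movements, 35 degrees apart."""
    return tuple(
        DF_START + DF_LENGTH * np.array([np.cos(b), np.sin(b)])
        for b in DF_BEARINGS
    )


def _reach_plans(cfg, center, n_dirs, length, duration, hold):
    plans = []
    for i in range(n_dirs):
        ang = 2 * np.pi * i / n_dirs
        goal = center + length * np.array([np.cos(ang), np.sin(ang)])
        plans.append(reach_plan(center, goal, duration, cfg, hold=hold))
    return plans


def states_from_plans(plans, stride: int = 5) -> np.ndarray:
    """Joint position/velocity states of the planned reference movements."""
    chunks = []
    for plan in plans:
        q = plan.q[0::2][::stride]
        qd = plan.qd[0::2][::stride]
        chunks.append(np.hstack([q, qd]))
    return np.vstack(chunks)


def initialization_states(
    plans, cfg: Config, seed: int, n_naive: int = 1, stride: int = 10,
    naive: bool = True,
) -> np.ndarray:
    """Joint states of the interaction-free condition.

    With ``naive=True`` the planned reference states are combined with the
    states actually visited when each movement is performed naively (zero
    feedforward weights, feedback only) in the null field: before any
    learning, demanding movements deviate far from their plan, and the
    network must carry activation fields along the entire naive path so
    the early error signal falls on basis support — and so that the
    learned mapping stays anchored off the reference manifold.  With
    ``naive=False`` only the planned trajectories are used, which keeps
    the basis tight around the task manifold (appropriate when the free
    movements are ordinary reaches the subject is already skilled at).
    """
    chunks = [states_from_plans(plans)]
    if naive:
        rng = np.random.default_rng(seed)
        probe = select_network(chunks[0], cfg.rbf, seed=seed)
        probe.W[:] = 0.0
        nf = null_field()
        for plan in plans:
            for _ in range(n_naive):
                res = simulate_trial(plan, probe, nf, cfg, rng=rng)
                chunks.append(np.hstack([res.q[::stride], res.qd[::stride]]))
    return np.vstack(chunks)


def network_for_plans(
    plans, cfg: Config, seed: int, naive: bool = True
) -> RBFNetwork:
    """Cluster the interaction-free states of ``plans`` into a network."""
    return select_network(
        initialization_states(plans, cfg, seed, naive=naive), cfg.rbf, seed=seed
    )


def _run_block(
    items, net, cfg, rng, learn=True, noise=True, history=None
) -> LearningHistory:
    if history is None:
        history = LearningHistory()
    for plan, fld in items:
        res = simulate_trial(plan, net, fld, cfg, rng=rng, noise=noise)
        if learn:
            apply_rbf_update(net, res, cfg)
        history.append(len(history.records), res, cfg, net)
    return history


def _probe_ratios(plan, net, cfg, fld, rng, n_probe):
    """Axis ratios of catch-trial circles (no learning)."""
    ratios, paths = [], []
    for _ in range(n_probe):
        res = simulate_trial(plan, net, fld, cfg, rng=rng, noise=True)
        ratios.append(axis_ratio(res.hand))
        paths.append(res.hand)
    return float(np.mean(ratios)), paths


# ---------------------------------------------------------------------------
# movement generalization (circle vs. reaches in a velocity-dependent field)


def run_conditt(
    cfg: Config | None = None,
    seed: int = 0,
    n_nf_train: int = 400,
    n_train: int = 100,
    n_probe: int = 5,
    n_train_circle: int | None = None,
) -> dict:
    """Transfer of velocity-field learning between reaches and circles.

    Builds the network from eight 12 cm reaches and the 10 cm circle in the
    null field, pre-trains it on those free movements, then runs two arms:
    direct circle training in the field, and reach-only training whose
    learning is probed on (never-trained) circles.  Returns axis ratios of
    the drawn circles in every phase.
    """
    cfg = cfg or default_config()
    ss = np.random.SeedSequence(seed)
    s_net, s_nf, s_direct, s_transfer, s_probe = [
        np.random.default_rng(c) for c in ss.spawn(5)
    ]
    reaches = _reach_plans(
        cfg, CENTER, 8, REACH_LENGTH, REACH_DURATION, REACH_HOLD
    )
    circle = circle_plan(CENTER, CIRCLE_RADIUS, CIRCLE_DURATION, cfg)
    net0 = network_for_plans(
        reaches + [circle], cfg, int(s_net.integers(2**31))
    )
    nf = null_field()
    vf = vf_field(cfg.fields)

    # free-condition pre-training on the same movements (mixed half/half
    # between the circle and the reaches; the fast circle needs the most
    # practice before free movements are accurate)
    def nf_item(_):
        if s_nf.random() < 0.5:
            return circle, nf
        return reaches[s_nf.integers(8)], nf

    _run_block((nf_item(i) for i in range(n_nf_train)), net0, cfg, s_nf)

    ratio_nf, paths_nf = _probe_ratios(circle, net0, cfg, nf, s_probe, n_probe)
    ratio_first, paths_first = _probe_ratios(
        circle, net0, cfg, vf, s_probe, n_probe
    )

    # arm A: learn the field directly on the circle
    if n_train_circle is None:
        n_train_circle = n_train
    net_direct = RBFNetwork.from_dict(net0.to_dict())
    hist_direct = _run_block(
        ((circle, vf) for _ in range(n_train_circle)), net_direct, cfg, s_direct
    )
    ratio_in_direct, paths_in_direct = _probe_ratios(
        circle, net_direct, cfg, vf, s_probe, n_probe
    )
    ratio_after_direct, paths_after_direct = _probe_ratios(
        circle, net_direct, cfg, nf, s_probe, n_probe
    )

    # arm B: learn the field with reaching movements only
    net_transfer = RBFNetwork.from_dict(net0.to_dict())
    reach_seq = _balanced_directions(s_transfer, 8, n_train)
    hist_transfer = _run_block(
        ((reaches[d], vf) for d in reach_seq),
        net_transfer, cfg, s_transfer,
    )
    ratio_in_transfer, paths_in_transfer = _probe_ratios(
        circle, net_transfer, cfg, vf, s_probe, n_probe
    )
    ratio_after_transfer, paths_after_transfer = _probe_ratios(
        circle, net_transfer, cfg, nf, s_probe, n_probe
    )

    # reach phases for the panel plot: early/late/after-effect reach paths
    reach_paths = {}
    df = hist_transfer.frame()
    reach_paths["early"] = [r.hand for r in hist_transfer.results[:8]]
    reach_paths["late"] = [r.hand for r in hist_transfer.results[-8:]]
    after_reach = []
    for plan in reaches:
        res = simulate_trial(plan, net_transfer, cfg=cfg, field=nf,
                             rng=s_probe, noise=True)
        after_reach.append(res.hand)
    reach_paths["after"] = after_reach

    return {
        "protocol": Protocol(
            "movement-generalization",
            [list(CENTER)], REACH_LENGTH, REACH_DURATION,
            {"nf_train": n_nf_train, "train": n_train, "probe": n_probe},
            vf.describe(), seed,
        ),
        "ratios": {
            "nf": ratio_nf,
            "first_exposure": ratio_first,
            "in_field_direct": ratio_in_direct,
            "in_field_transfer": ratio_in_transfer,
            "after_direct": ratio_after_direct,
            "after_transfer": ratio_after_transfer,
        },
        "paths": {
            "nf": paths_nf,
            "first_exposure": paths_first,
            "in_field_direct": paths_in_direct,
            "in_field_transfer": paths_in_transfer,
            "after_direct": paths_after_direct,
            "after_transfer": paths_after_transfer,
            "reach": reach_paths,
        },
        "history_direct": hist_direct.frame(),
        "history_transfer": df,
        "network": net_transfer.to_dict(),
    }


# ---------------------------------------------------------------------------
# granularity of the feedforward model (VF1 / VF2 / VF4)


def _balanced_directions(rng, n_dirs, n_trials):
    """Randomly ordered targets, balanced in blocks of ``n_dirs``."""
    reps = int(np.ceil(n_trials / n_dirs))
    seq = np.concatenate([rng.permutation(n_dirs) for _ in range(reps)])
    return seq[:n_trials]


def run_thoroughman(
    cfg: Config | None = None,
    seed: int = 0,
    ks=(1, 2, 4),
    n_nf: int = 80,
    n_field: int = 160,
    n_dirs: int = 16,
    n_nf_pre: int = 200,
) -> dict:
    """Learning of direction-variant curl fields of increasing granularity.

    80 free movements to randomly ordered targets in 16 directions are
    followed, for each spatial frequency k, by 160 movements in VFk (same
    network size and activation fields for all fields).  The learning curve
    is the velocity correlation against the same-direction free-movement
    template, smoothed with a 20-movement moving average.
    """
    cfg = cfg or default_config()
    ss = np.random.SeedSequence(seed)
    rngs = ss.spawn(2 + len(ks))
    s_nf = np.random.default_rng(rngs[0])
    reaches = _reach_plans(
        cfg, CENTER, n_dirs, REACH_LENGTH, REACH_DURATION, REACH_HOLD
    )
    net_seed = int(np.random.default_rng(rngs[1]).integers(2**31))
    net0 = network_for_plans(reaches, cfg, net_seed, naive=False)
    nf = null_field()
    n_mv = int(round(REACH_DURATION / cfg.simulation.dt)) + 1

    # pre-training: the simulated subject arrives skilled at free reaching
    _run_block(
        ((reaches[d], nf) for d in s_nf.integers(n_dirs, size=n_nf_pre)),
        net0, cfg, s_nf,
    )

    # free phase proper: train and collect per-direction velocity templates
    dirs_nf = _balanced_directions(s_nf, n_dirs, n_nf)
    nf_hist = _run_block(
        ((reaches[d], nf) for d in dirs_nf), net0, cfg, s_nf
    )
    templates = {}
    for d in range(n_dirs):
        vels = [
            nf_hist.results[i].hand_vel[:n_mv]
            for i in np.flatnonzero(dirs_nf == d)
        ]
        templates[d] = np.mean(vels, axis=0) if vels else None
    nf_corr = [
        velocity_correlation(nf_hist.results[i].hand_vel[:n_mv], templates[d])
        for i, d in enumerate(dirs_nf)
        if templates[d] is not None
    ]

    out = {
        "protocol": Protocol(
            "granularity", list(range(n_dirs)), REACH_LENGTH,
            REACH_DURATION,
            {"nf": n_nf, "field": n_field}, {"ks": list(ks)}, seed,
        ),
        "nf_correlation": float(np.nanmean(nf_corr)),
        "correlation_curves": {},
        "final_correlation": {},
        "after_effect_deviation": {},
        "paths": {},
    }

    for j, k in enumerate(ks):
        rng = np.random.default_rng(rngs[2 + j])
        net = RBFNetwork.from_dict(net0.to_dict())
        fld = vfk_field(cfg.fields, k)
        corr = []
        paths_before, paths_after = [], []
        dirs_seq = _balanced_directions(rng, n_dirs, n_field)
        for t_idx, d in enumerate(dirs_seq):
            ang = 2 * np.pi * d / n_dirs
            res = simulate_trial(
                reaches[d], net, fld.with_direction(ang), cfg, rng=rng
            )
            apply_rbf_update(net, res, cfg)
            c = (
                velocity_correlation(res.hand_vel[:n_mv], templates[d])
                if templates[d] is not None
                else np.nan
            )
            corr.append(c)
            if t_idx < n_dirs:
                paths_before.append(res.hand)
            if t_idx >= n_field - n_dirs:
                paths_after.append(res.hand)
        smoothed = smooth_curve(corr, 20)
        # after-effects: field silently removed, one catch trial per direction
        aftereffects = []
        ae_paths = []
        for d in range(0, n_dirs, 2):
            res = simulate_trial(reaches[d], net, nf, cfg, rng=rng)
            aftereffects.append(float(np.max(np.abs(res.lateral_deviation()))))
            ae_paths.append(res.hand)
        out["correlation_curves"][k] = smoothed
        out["final_correlation"][k] = float(smoothed[-1])
        out["after_effect_deviation"][k] = float(np.mean(aftereffects))
        out["paths"][k] = {
            "before": paths_before, "after": paths_after,
            "aftereffect": ae_paths,
        }
    return out


# ---------------------------------------------------------------------------
# impedance learning in multiple movements (divergent field)


def _upsample_half_grid(a: np.ndarray) -> np.ndarray:
    """Linear upsampling from the step grid (n+1) to the half grid (2n+1)."""
    n = a.shape[0] - 1
    out = np.empty((2 * n + 1,) + a.shape[1:])
    out[0::2] = a
    out[1::2] = 0.5 * (a[:-1] + a[1:])
    return out


def _muscle_length_traj(res, cfg):
    A = cfg.geometry.moment_arms
    l = cfg.geometry.l0 - (res.q - cfg.geometry.q_ref) @ A
    ld = -res.qd @ A
    return _upsample_half_grid(l), _upsample_half_grid(ld)


def _mid_movement_activation(results, n_mv):
    """Mean total activation over the middle third of recent trials."""
    lo, hi = n_mv // 3, 2 * n_mv // 3
    return np.mean([r.u[lo:hi].mean(axis=0) for r in results], axis=0)


def _corridor_plans(cfg, start, goal, duration, hold, offsets):
    """Reference movements spanning the lateral variability corridor.

    The unstable task explores a tube around the straight path (trial-to-
    trial variability is amplified laterally up to the safety barrier), so
    the network's activation fields must cover that corridor.  Each
    corridor plan follows the straight minimum-jerk path plus a smooth
    lateral bump of amplitude ``offset`` peaking at mid-movement.
    """
    axis = np.asarray(goal) - np.asarray(start)
    l_hat = np.array([-axis[1], axis[0]]) / np.linalg.norm(axis)
    base = reach_plan(start, goal, duration, cfg, hold=hold)
    plans = [base]
    t = base.times()
    # smooth rise to full displacement by mid-movement, held thereafter
    # (the unstable task can park the hand laterally displaced near the
    # goal, so the corridor must cover displaced hold states too)
    s = np.clip(t / (0.5 * duration), 0.0, 1.0)
    ramp = 3 * s**2 - 2 * s**3
    from .controller import _plan_from_hand

    for off in offsets:
        hand = base.hand + np.outer(off * ramp, l_hat)
        vel = np.zeros_like(hand)
        vel[:, 0] = np.gradient(hand[:, 0], t)
        vel[:, 1] = np.gradient(hand[:, 1], t)
        plans.append(
            _plan_from_hand(
                "corridor", base.start, base.goal, base.duration,
                hand, vel, base.dt, cfg,
            )
        )
    return plans


def run_kadiallah(
    cfg: Config | None = None,
    seed: int = 0,
    n_nf: int = 60,
    n_df: int = 300,
    n_mean: int | None = None,
) -> dict:
    """Impedance learning for two movement directions in a divergent field.

    600 ms point-to-point movements to two targets 35 degrees apart are
    randomly intermixed for ``n_df`` trials in the unstable field.  The
    motion error is taken relative to the mean of the last ``n_mean``
    successful trials of the same target (warm-started with the minimum-jerk
    path).  Endpoint stiffness ellipses are computed from mid-movement
    activation before and after learning.
    """
    cfg = cfg or default_config()
    ss = np.random.SeedSequence(seed)
    r_net, r_nf, r_df = [np.random.default_rng(c) for c in ss.spawn(3)]
    goals = df_goals()
    base_plans = [
        reach_plan(DF_START, g, DF_DURATION, cfg, hold=DF_HOLD) for g in goals
    ]
    offsets = (-0.05, -0.03, -0.015, 0.015, 0.03, 0.05)
    corridor = [
        p
        for g in goals
        for p in _corridor_plans(cfg, DF_START, g, DF_DURATION, DF_HOLD, offsets)
    ]
    net = select_network(
        states_from_plans(corridor), cfg.rbf, seed=int(r_net.integers(2**31))
    )
    nf = null_field()
    n_mv = int(round(DF_DURATION / cfg.simulation.dt)) + 1
    end_radius = cfg.fields.endzone_diameter / 2

    # free-condition training
    dirs_nf = _balanced_directions(r_nf, 2, n_nf)
    hist_nf = _run_block(
        ((base_plans[d], nf) for d in dirs_nf), net, cfg, r_nf
    )
    stiff_before = {}
    for d in (0, 1):
        recent = [
            hist_nf.results[i]
            for i in np.flatnonzero(dirs_nf == d)[-10:]
        ]
        u_mid = _mid_movement_activation(recent, n_mv)
        q_mid = base_plans[d].q[base_plans[d].q.shape[0] // 2]
        stiff_before[d] = endpoint_stiffness(u_mid, q_mid, cfg)

    # divergent-field phase; optionally with empirical-mean error references
    # (n_mean successful trials averaged; default: planned-path reference)
    ref_store = {0: deque(maxlen=n_mean or 1), 1: deque(maxlen=n_mean or 1)}
    fields = [df_field(cfg.fields, DF_START, g) for g in goals]
    hist_df = LearningHistory()
    early_paths = {0: [], 1: []}
    late_paths = {0: [], 1: []}
    success = []
    dirs_df = _balanced_directions(r_df, 2, n_df)
    for t_idx, d in enumerate(dirs_df):
        store = ref_store[d]
        if n_mean is not None and len(store) == n_mean:
            # enough successful trials for a stable empirical mean; it
            # defines the motion error while the planned path keeps the
            # mechanical equilibrium
            err_plan = mean_trajectory_plan(
                base_plans[d], [x[0] for x in store], [x[1] for x in store]
            )
        else:
            err_plan = None
        res = simulate_trial(
            base_plans[d], net, fields[d], cfg, rng=r_df, error_plan=err_plan
        )
        ok = (not res.aborted) and res.terminal_error() <= end_radius
        success.append(ok)
        if ok:
            store.append(_muscle_length_traj(res, cfg))
        apply_rbf_update(net, res, cfg)
        hist_df.append(t_idx, res, cfg, net, extra={"success": ok, "dir": int(d)})
        if t_idx < 20:
            early_paths[d].append(res.hand)
        if t_idx >= n_df - 20:
            late_paths[d].append(res.hand)

    stiff_after = {}
    lateral_angle = {}
    for d in (0, 1):
        recent = [
            hist_df.results[i]
            for i in np.flatnonzero(dirs_df == d)[-10:]
        ]
        u_mid = _mid_movement_activation(recent, n_mv)
        q_mid = base_plans[d].q[base_plans[d].q.shape[0] // 2]
        stiff_after[d] = endpoint_stiffness(u_mid, q_mid, cfg)
        axis = goals[d] - DF_START
        lateral = np.array([-axis[1], axis[0]])
        lateral_angle[d] = float(
            np.degrees(np.arctan2(lateral[1], lateral[0])) % 180.0
        )

    return {
        "protocol": Protocol(
            "impedance-learning", [g.tolist() for g in goals], DF_LENGTH,
            DF_DURATION, {"nf": n_nf, "df": n_df},
            fields[0].describe(), seed,
        ),
        "stiffness_before": stiff_before,
        "stiffness_after": stiff_after,
        "lateral_angle": lateral_angle,
        "success_rate": float(np.mean(success)),
        "early_paths": early_paths,
        "late_paths": late_paths,
        "history": hist_df.frame(),
        "network": net.to_dict(),
    }


def experiment_state_sets(cfg: Config | None = None, seed: int = 0) -> dict:
    """The interaction-free joint-state data of each experiment.

    Used to size the network: eight reaches plus the circle (movement
    generalization), sixteen reaches (granularity), and the two movements
    35 degrees apart (impedance learning).
    """
    cfg = cfg or default_config()
    conditt = _reach_plans(
        cfg, CENTER, 8, REACH_LENGTH, REACH_DURATION, REACH_HOLD
    ) + [circle_plan(CENTER, CIRCLE_RADIUS, CIRCLE_DURATION, cfg)]
    thoroughman = _reach_plans(
        cfg, CENTER, 16, REACH_LENGTH, REACH_DURATION, REACH_HOLD
    )
    offsets = (-0.05, -0.03, -0.015, 0.015, 0.03, 0.05)
    kadiallah = [
        p
        for g in df_goals()
        for p in _corridor_plans(cfg, DF_START, g, DF_DURATION, DF_HOLD, offsets)
    ]
    return {
        "movement-generalization": initialization_states(conditt, cfg, seed),
        "granularity": initialization_states(thoroughman, cfg, seed, naive=False),
        "impedance-learning": states_from_plans(kadiallah),
    }
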