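"""Trial-by-trial gradient-descent adaptation of the feedforward command.

The feedforward command is linear in its non-negative parameters,
``u_ff = Phi(x) w``, for any basis ``Phi`` (the RBF network is one such
basis).  Between trials the parameters descend the cost

    J(w) = Q/2 * sum_t ||u_fb(t)||^2 dt  +  R * ||w||_1

where ``u_fb`` is the V-shaped feedback command.  Under the feedback-
absorption assumption — each unit of feedforward activation removes one unit
of the feedback that had to correct for it, ``d u_fb / d w = -Phi`` — the
descent step is

    delta_w = eta * Q * sum_t Phi(x_t)^T v(s(t)) dt  -  eta * R * 1,

with ``v`` the V-shape (``v(s) = a+ s+ - a- s-``) applied to the
*delay-compensated* sliding error ``s(t) = e(t) + kappa edot(t)`` (the
sliding error one delay ahead, aligned with the state that caused it), and a
uniform decay from the l1 effort term.  Splitting ``v`` into odd and even
parts decomposes the update into a signed *reciprocal* term that opposes
systematic error, a non-negative *co-activation* term that stiffens the limb
in response to deviation of either sign, and the uniform decay that removes
superfluous (co-)activation — a winner-take-all scheme extinguishing the
least supported parameters first.  Weights are clipped at zero after every
update (activations cannot be negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .config import Config, LearningConfig
from .controller import VShapeGains
from .rbf import RBFNetwork
from .simulate import TrialResult, simulate_trial

__all__ = [
    "UpdateDecomposition",
    "cost",
    "error_drive",
    "gradient_update",
    "decompose_update",
    "apply_rbf_update",
    "run_learning",
    "LearningHistory",
]


@dataclass
class UpdateDecomposition:
    """The applied update split into its three mechanisms.

    ``reciprocal + coactivation + decay == applied`` exactly; the decay term
    absorbs the clipping at zero and is never positive.
    """

    reciprocal: np.ndarray
    coactivation: np.ndarray
    decay: np.ndarray

    @property
    def applied(self) -> np.ndarray:
        return self.reciprocal + self.coactivation + self.decay


def error_drive(s: np.ndarray, gains: VShapeGains) -> np.ndarray:
    """V-shaped error drive ``v(s) = a+ s+ - a- s-`` (non-negative)."""
    s = np.asarray(s, dtype=float)
    return (
        gains.stretch_slope * np.maximum(s, 0.0)
        - gains.shortening_slope * np.minimum(s, 0.0)
    )


def cost(
    s_traj: np.ndarray,
    u_ff_traj: np.ndarray,
    cfg: LearningConfig,
    gains: VShapeGains,
    dt: float,
) -> float:
    """Scalar cost of one trial: feedback-error term plus effort term.

    ``J = Q/2 sum_t ||v(s)||^2 dt + R sum_t 1^T u_ff dt``.  The effort term
    is linear in the command, so scaling ``u_ff`` by ``c`` scales it by
    ``c`` exactly.
    """
    s_traj = np.asarray(s_traj, dtype=float)
    u_ff_traj = np.asarray(u_ff_traj, dtype=float)
    if s_traj.shape[0] != u_ff_traj.shape[0]:
        raise ValueError("error and activation trajectories must be aligned")
    v = error_drive(s_traj, gains)
    return float(
        0.5 * cfg.error_weight * np.sum(v * v) * dt
        + cfg.effort_weight * np.sum(u_ff_traj) * dt
    )


def gradient_update(
    w: np.ndarray,
    phi_traj: np.ndarray,
    s_traj: np.ndarray,
    cfg: LearningConfig,
    gains: VShapeGains,
    dt: float,
):
    """One between-trial update of the parameter vector.

    ``phi_traj`` has shape (T, n_muscles, P); ``s_traj`` (T, n_muscles) is
    the delay-compensated sliding error.  Returns the clipped new weights
    and the update decomposition.  A trial containing non-finite errors is
    discarded (weights unchanged).
    """
    w = np.asarray(w, dtype=float)
    phi_traj = np.asarray(phi_traj, dtype=float)
    s_traj = np.asarray(s_traj, dtype=float)
    if not np.all(np.isfinite(s_traj)):
        import warnings

        warnings.warn("non-finite error trajectory: trial discarded, no update")
        P = w.shape[0]
        zero = np.zeros(P)
        return w.copy(), UpdateDecomposition(zero, zero.copy(), zero.copy())

    alpha = 0.5 * (gains.stretch_slope - gains.shortening_slope)
    beta = 0.5 * (gains.stretch_slope + gains.shortening_slope)
    scale = cfg.rate * cfg.error_weight * dt
    rec = scale * np.einsum("tmp,tm->p", phi_traj, alpha * s_traj)
    coact = scale * np.einsum("tmp,tm->p", phi_traj, beta * np.abs(s_traj))
    w_new = np.maximum(w + rec + coact - cfg.decay, 0.0)
    decay = (w_new - w) - rec - coact
    return w_new, UpdateDecomposition(rec, coact, decay)


def decompose_update(
    delta_w: np.ndarray,
    s_traj: np.ndarray,
    phi_traj: np.ndarray,
    cfg: LearningConfig,
    gains: VShapeGains,
    dt: float,
) -> UpdateDecomposition:
    """Split an applied update into reciprocal, co-activation and decay.

    The first two terms are recomputed from the error trajectory; the decay
    term is the exact remainder, so the three always sum to ``delta_w``.
    """
    alpha = 0.5 * (gains.stretch_slope - gains.shortening_slope)
    beta = 0.5 * (gains.stretch_slope + gains.shortening_slope)
    scale = cfg.rate * cfg.error_weight * dt
    rec = scale * np.einsum("tmp,tm->p", phi_traj, alpha * np.asarray(s_traj))
    coact = scale * np.einsum(
        "tmp,tm->p", phi_traj, beta * np.abs(np.asarray(s_traj))
    )
    return UpdateDecomposition(rec, coact, np.asarray(delta_w) - rec - coact)


def apply_rbf_update(
    net: RBFNetwork, result: TrialResult, cfg: Config
) -> UpdateDecomposition:
    """Apply the learning law to an RBF network from one trial's logs.

    Uses the drive accumulators the simulator collected:
    ``Gs = sum_t outer(s, g) dt`` and ``Gabs = sum_t outer(|s|, g) dt``.
    Identical to :func:`gradient_update` on the flattened weight vector with
    ``Phi = kron(I, g^T)`` — an identity the test suite asserts.
    """
    lc = cfg.learning
    gains = cfg.feedback
    if result.aborted or not np.all(np.isfinite(result.Gs)):
        zero = np.zeros_like(net.W)
        return UpdateDecomposition(zero, zero.copy(), zero.copy())
    alpha = 0.5 * (gains.stretch_slope - gains.shortening_slope)
    beta = 0.5 * (gains.stretch_slope + gains.shortening_slope)
    scale = lc.rate * lc.error_weight
    rec = scale * alpha * result.Gs
    coact = scale * beta * result.Gabs
    W_new = np.maximum(net.W + rec + coact - lc.decay, 0.0)
    decomp = UpdateDecomposition(rec, coact, (W_new - net.W) - rec - coact)
    net.W = W_new
    return decomp


@dataclass
class LearningHistory:
    """Per-trial summary of a learning run."""

    records: list = dc_field(default_factory=list)
    results: list = dc_field(default_factory=list)

    def append(self, trial_idx, result: TrialResult, cfg: Config, net,
               extra=None):
        lc = cfg.learning
        rec = {
            "trial": trial_idx,
            "kind": result.plan.kind,
            "field": result.field.variant,
            "aborted": result.aborted,
            "cost": cost(result.s, result.u_ff, lc, cfg.feedback, result.plan.dt),
            "error_norm": float(np.sqrt(np.mean(result.s**2))),
            "max_lateral": float(np.max(np.abs(result.lateral_deviation())))
            if result.plan.kind != "circle"
            else np.nan,
            "weight_norm": float(np.linalg.norm(net.W)),
            "coactivation": float(np.sum(np.minimum(net.W[0::2], net.W[1::2]))),
        }
        if extra:
            rec.update(extra)
        self.records.append(rec)
        self.results.append(result)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(self.records)


def run_learning(
    protocol,
    net: RBFNetwork,
    cfg: Config,
    seed: int | np.random.Generator = 0,
    noise: bool = True,
    learn: bool = True,
    history: LearningHistory | None = None,
) -> LearningHistory:
    """Simulate a sequence of trials, updating the network between trials.

    ``protocol`` is an iterable of ``(plan, field)`` pairs (or a callable
    ``trial_index -> (plan, field)`` paired with a length via ``(fn, n)``).
    Aborted trials are logged and skipped by the learning update.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if history is None:
        history = LearningHistory()
    if isinstance(protocol, tuple) and callable(protocol[0]):
        fn, n_trials = protocol
        items = (fn(i) for i in range(n_trials))
    else:
        items = protocol
    for idx, (plan, field) in enumerate(items):
        result = simulate_trial(plan, net, field, cfg, rng=rng, noise=noise)
        if learn:
            apply_rbf_update(net, result, cfg)
        history.append(idx, result, cfg, net)
    return history
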