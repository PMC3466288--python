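"""Outcome metrics: circle distortion, velocity correlation, endpoint
stiffness.

The three measures quantify the three experiments: the horizontal/vertical
axis ratio of a drawn circle (movement-generalization), the Pearson
correlation between a trial's velocity time series and its null-field
template smoothed with a 20-movement moving average (field granularity), and
the 2x2 endpoint stiffness matrix with its ellipse (impedance learning).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Config
from .plant import jacobian

__all__ = [
    "StiffnessEllipse",
    "axis_ratio",
    "velocity_correlation",
    "smooth_curve",
    "endpoint_stiffness",
]


def axis_ratio(path: np.ndarray) -> float:
    """Ratio of horizontal to vertical extent of a drawn path.

    ``(max x - min x) / (max y - min y)``; 1.0 for an undistorted circle,
    below 1 for a vertically elongated one.
    """
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[0] < 8:
        raise ValueError("need at least 8 path points")
    ext = path.max(axis=0) - path.min(axis=0)
    if ext[1] < 1e-9:
        raise ValueError("degenerate path: no vertical extent")
    return float(ext[0] / ext[1])


def velocity_correlation(
    vel: np.ndarray, template: np.ndarray
) -> float:
    """Pearson correlation of 2-D velocity time series against a template.

    The two series are resampled to a common grid if their lengths differ;
    the x and y components are concatenated before correlating.  Returns
    NaN when either series has no variance.
    """
    vel = np.asarray(vel, dtype=float)
    template = np.asarray(template, dtype=float)
    if vel.shape[0] != template.shape[0]:
        n = max(vel.shape[0], template.shape[0])
        t = np.linspace(0.0, 1.0, n)

        def resample(a):
            src = np.linspace(0.0, 1.0, a.shape[0])
            return np.stack([np.interp(t, src, a[:, j]) for j in range(2)], axis=1)

        vel, template = resample(vel), resample(template)
    a = vel.T.reshape(-1)
    b = template.T.reshape(-1)
    if np.std(a) < 1e-12 or np.std(b) < 1e-12:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def smooth_curve(values, window: int = 20) -> np.ndarray:
    """Moving average over trials (20-movement window by default)."""
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window, min_periods=1).mean().to_numpy()


@dataclass
class StiffnessEllipse:
    """Endpoint stiffness matrix with its ellipse descriptors."""

    K: np.ndarray              # 2x2 endpoint stiffness (N/m)
    eigvals: np.ndarray        # eigenvalues of the symmetric part, desc.
    orientation_deg: float     # major-axis angle in [0, 180) deg from +x
    area: float                # pi * sqrt(prod(|eigvals|))

    @classmethod
    def from_matrix(cls, K: np.ndarray) -> "StiffnessEllipse":
        K = np.asarray(K, dtype=float)
        Ks = 0.5 * (K + K.T)
        vals, vecs = np.linalg.eigh(Ks)
        order = np.argsort(vals)[::-1]
        vals = vals[order]
        major = vecs[:, order[0]]
        ang = np.degrees(np.arctan2(major[1], major[0])) % 180.0
        return cls(K, vals, float(ang), float(np.pi * np.sqrt(np.abs(vals.prod()))))


def endpoint_stiffness(
    u: np.ndarray,
    q: np.ndarray,
    cfg: Config,
    include_feedback: bool = True,
) -> StiffnessEllipse:
    """Endpoint stiffness from the muscle activations at posture ``q``.

    Each muscle contributes its intrinsic stiffness ``k0 + k1 u`` plus, when
    ``include_feedback`` is set, the steady-state reflex pathway.  A static
    displacement stretches a muscle (raising its tension at V-slope ``a+``)
    and shortens its antagonist (which the V-shape *also* activates, at
    slope ``a-`` — but that tension acts along the displacement).  The net
    first-order reflex stiffness per muscle is therefore the reciprocal
    half of the V-shape, ``(a+ - a-)/2 * T0``; the co-activation half
    produces a restoring-free tension bias.  Joint stiffness is
    ``A diag(k) A^T`` and maps to the hand as ``K_e = J^-T K_joint J^-1``.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("activations must be non-negative")
    k = cfg.muscle.stiffness(u)
    if include_feedback:
        slope = 0.5 * (cfg.feedback.stretch_slope - cfg.feedback.shortening_slope)
        k = k + slope * cfg.muscle.T0
    A = cfg.geometry.moment_arms
    K_joint = A @ np.diag(k) @ A.T
    J = jacobian(q, cfg.arm)
    if abs(np.linalg.det(J)) < 1e-8:
        raise ValueError("singular posture: endpoint stiffness undefined")
    Jinv = np.linalg.inv(J)
    K_e = Jinv.T @ K_joint @ Jinv
    return StiffnessEllipse.from_matrix(K_e)
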