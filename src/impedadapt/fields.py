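"""Simulated dynamic environments applied at the hand.

Four families: the null field NF; a velocity-dependent field VF (endpoint
force linear in hand velocity through a constant gain matrix); its
direction-variant versions VF1/VF2/VF4, whose curl gain is modulated by the
planned movement direction at spatial frequency k; and a position-dependent
divergent field DF that pushes the hand away from the straight start-goal
line (negative lateral stiffness), fitted with a safety barrier of pure
damping beyond a lateral threshold and force-free start/end circles.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .config import FieldDefaults

__all__ = [
    "ForceFieldSpec",
    "null_field",
    "vf_field",
    "vfk_field",
    "df_field",
    "vf_force",
    "vfk_force",
    "df_force",
]

_CURL = np.array([[0.0, -1.0], [1.0, 0.0]])


@dataclass(frozen=True)
class ForceFieldSpec:
    """Tagged description of one environment.

    ``variant`` is one of ``"NF" | "VF" | "VFK" | "DF"``.  For VFK the
    movement direction (set per trial by the protocol driver) selects the
    signed curl gain; for DF the start/goal pair defines the instability
    axis.
    """

    variant: str
    matrix: np.ndarray | None = None          # VF gain (N s/m)
    gain: float = 0.0                          # VFK amplitude or DF stiffness
    k: int = 0                                 # VFK spatial frequency
    direction: float = 0.0                     # planned movement angle (rad)
    start: np.ndarray | None = None            # DF line start (m)
    goal: np.ndarray | None = None             # DF line goal (m)
    barrier_threshold: float = 0.05            # m
    barrier_damping: float = 50.0              # N s/m
    endzone_diameter: float = 0.025            # m
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.variant not in ("NF", "VF", "VFK", "DF"):
            raise ValueError(f"unknown field variant {self.variant!r}")
        if self.variant == "VFK" and self.k not in (1, 2, 4):
            raise ValueError("VFK spatial frequency k must be in {1, 2, 4}")
        if self.variant == "DF":
            if self.start is None or self.goal is None:
                raise ValueError("DF requires start and goal points")
            if self.barrier_threshold <= 0:
                raise ValueError("DF barrier threshold must be positive")

    def with_direction(self, direction: float) -> "ForceFieldSpec":
        return ForceFieldSpec(
            self.variant, self.matrix, self.gain, self.k, direction,
            self.start, self.goal, self.barrier_threshold,
            self.barrier_damping, self.endzone_diameter, dict(self.meta),
        )

    def with_endpoints(self, start, goal) -> "ForceFieldSpec":
        return ForceFieldSpec(
            self.variant, self.matrix, self.gain, self.k, self.direction,
            np.asarray(start, float), np.asarray(goal, float),
            self.barrier_threshold, self.barrier_damping,
            self.endzone_diameter, dict(self.meta),
        )

    def force(self, p: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Endpoint force (N) at hand position ``p`` and velocity ``v``."""
        if self.variant == "NF":
            return np.zeros(2)
        if self.variant == "VF":
            return vf_force(v, self.matrix)
        if self.variant == "VFK":
            return vfk_force(v, self.direction, self.k, self.gain)
        return df_force(p, v, self)

    def describe(self) -> dict:
        """Serializable description embedded in every trial log header."""
        d = {"variant": self.variant, "gain": self.gain, "k": self.k}
        if self.matrix is not None:
            d["matrix"] = np.asarray(self.matrix).tolist()
        if self.start is not None:
            d["start"] = np.asarray(self.start).tolist()
            d["goal"] = np.asarray(self.goal).tolist()
            d["barrier_threshold"] = self.barrier_threshold
            d["barrier_damping"] = self.barrier_damping
            d["endzone_diameter"] = self.endzone_diameter
        return d


def null_field() -> ForceFieldSpec:
    return ForceFieldSpec("NF")


def vf_field(defaults: FieldDefaults, matrix=None) -> ForceFieldSpec:
    B = defaults.vf_matrix if matrix is None else np.asarray(matrix, float)
    return ForceFieldSpec("VF", matrix=B)


def vfk_field(defaults: FieldDefaults, k: int, gain=None) -> ForceFieldSpec:
    return ForceFieldSpec(
        "VFK", gain=defaults.vfk_gain if gain is None else gain, k=int(k)
    )


def df_field(defaults: FieldDefaults, start, goal, gain=None) -> ForceFieldSpec:
    return ForceFieldSpec(
        "DF",
        gain=defaults.df_gain if gain is None else gain,
        start=np.asarray(start, float),
        goal=np.asarray(goal, float),
        barrier_threshold=defaults.barrier_threshold,
        barrier_damping=defaults.barrier_damping,
        endzone_diameter=defaults.endzone_diameter,
    )


# ---------------------------------------------------------------------------
# force laws


def vf_force(v: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Velocity-dependent force ``F = B v``."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("hand velocity must be finite")
    return np.asarray(B, dtype=float) @ v


def vfk_curl_gain(direction: float, k: int, gain: float) -> float:
    """Signed curl gain for movement direction ``direction`` (rad).

    ``b(theta) = gain * sin(k theta)`` — periodic with period ``2 pi / k``,
    so higher k flips the field sign between ever closer target directions.
    """
    if k not in (1, 2, 4):
        raise ValueError("k must be in {1, 2, 4}")
    return gain * np.sin(k * direction)


def vfk_force(v: np.ndarray, direction: float, k: int, gain: float) -> np.ndarray:
    """Direction-variant curl force ``F = b(theta) [[0,-1],[1,0]] v``."""
    return vfk_curl_gain(direction, k, gain) * (_CURL @ np.asarray(v, float))


def df_force(p: np.ndarray, v: np.ndarray, spec: ForceFieldSpec) -> np.ndarray:
    """Divergent force normal to the start-goal line.

    ``F_normal = gain * p_lat`` (destabilizing: same sign as the lateral
    deviation), ``F_parallel = 0``.  Lateral deviation is positive to the
    left of the start->goal direction.  Zero inside the start/end circles;
    beyond the barrier threshold the negative stiffness is replaced by
    damping opposing the lateral velocity.
    """
    p = np.asarray(p, dtype=float)
    v = np.asarray(v, dtype=float)
    axis = spec.goal - spec.start
    n_hat = axis / np.linalg.norm(axis)
    l_hat = np.array([-n_hat[1], n_hat[0]])  # left of travel
    r_end = spec.endzone_diameter / 2
    if (
        np.linalg.norm(p - spec.start) < r_end
        or np.linalg.norm(p - spec.goal) < r_end
    ):
        return np.zeros(2)
    p_lat = float(l_hat @ (p - spec.start))
    if abs(p_lat) <= spec.barrier_threshold:
        return spec.gain * p_lat * l_hat
    return -spec.barrier_damping * float(l_hat @ v) * l_hat
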