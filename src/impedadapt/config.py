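"""Configuration loading and validation.

Every physical and algorithmic parameter of the simulator lives in one
structured YAML file (``impedadapt/data/default.yaml`` ships the defaults).
Sections map one-to-one onto the dataclasses below; unknown keys and
out-of-range values are rejected with the offending key named.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ArmParameters",
    "MuscleGeometry",
    "MuscleParameters",
    "NoiseConfig",
    "FeedbackConfig",
    "LearningConfig",
    "RBFConfig",
    "FieldDefaults",
    "SimulationConfig",
    "Config",
    "ConfigError",
    "load_config",
    "default_config",
]

N_MUSCLES = 6


class ConfigError(ValueError):
    """Raised for missing, unknown, or out-of-range configuration entries."""


def _require_positive(name: str, value) -> None:
    if not np.all(np.isfinite(value)) or not np.all(np.asarray(value) > 0):
        raise ConfigError(f"{name} must be finite and strictly positive, got {value!r}")


def _require_nonnegative(name: str, value) -> None:
    if not np.all(np.isfinite(value)) or not np.all(np.asarray(value) >= 0):
        raise ConfigError(f"{name} must be finite and non-negative, got {value!r}")


@dataclass(frozen=True)
class ArmParameters:
    """Rigid-body parameters of the planar two-link arm (horizontal plane)."""

    l1: float = 0.31
    l2: float = 0.34
    m1: float = 1.93
    m2: float = 1.52
    lc1: float = 0.165
    lc2: float = 0.19
    I1: float = 0.0141
    I2: float = 0.0188
    viscosity: np.ndarray = field(
        default_factory=lambda: np.array([[0.80, 0.20], [0.20, 0.80]])
    )
    q_min: np.ndarray = field(default_factory=lambda: np.array([-0.30, 0.05]))
    q_max: np.ndarray = field(default_factory=lambda: np.array([2.80, 2.80]))

    def __post_init__(self):
        for name in ("l1", "l2", "m1", "m2", "lc1", "lc2", "I1", "I2"):
            _require_positive(f"arm.{name}", getattr(self, name))
        B = np.asarray(self.viscosity, dtype=float)
        if B.shape != (2, 2):
            raise ConfigError("arm.viscosity must be a 2x2 matrix")
        if not np.allclose(B, B.T):
            raise ConfigError("arm.viscosity must be symmetric")
        if np.any(np.linalg.eigvalsh(B) < -1e-12):
            raise ConfigError("arm.viscosity must be positive semi-definite")
        object.__setattr__(self, "viscosity", B)
        object.__setattr__(self, "q_min", np.asarray(self.q_min, dtype=float))
        object.__setattr__(self, "q_max", np.asarray(self.q_max, dtype=float))
        if np.any(self.q_min >= self.q_max):
            raise ConfigError("arm.q_min must be below arm.q_max componentwise")


@dataclass(frozen=True)
class MuscleGeometry:
    """Constant moment arms and reference lengths of the six muscles.

    Columns: shoulder flexor/extensor, elbow flexor/extensor, biarticular
    flexor/extensor.  Muscle lengths are linearized about ``q_ref``:
    ``l = l0 - A.T (q - q_ref)``.
    """

    moment_arms: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.040, -0.040, 0.000, 0.000, 0.028, -0.028],
                [0.000, 0.000, 0.025, -0.025, 0.028, -0.028],
            ]
        )
    )
    l0: np.ndarray = field(
        default_factory=lambda: np.array([0.13, 0.13, 0.11, 0.11, 0.26, 0.26])
    )
    q_ref: np.ndarray = field(default_factory=lambda: np.array([1.0472, 1.5708]))

    def __post_init__(self):
        A = np.asarray(self.moment_arms, dtype=float)
        if A.shape != (2, N_MUSCLES):
            raise ConfigError("geometry.moment_arms must be 2x6")
        # monoarticular columns touch exactly one joint; biarticular both
        for j in range(4):
            if np.count_nonzero(A[:, j]) != 1:
                raise ConfigError(
                    f"geometry.moment_arms column {j} must be monoarticular"
                )
        for j in (4, 5):
            if np.count_nonzero(A[:, j]) != 2:
                raise ConfigError(
                    f"geometry.moment_arms column {j} must be biarticular"
                )
        for a, b in ((0, 1), (2, 3), (4, 5)):
            if np.any(np.sign(A[:, a]) * np.sign(A[:, b]) > 0):
                raise ConfigError(
                    f"geometry.moment_arms columns {a},{b} must be antagonists"
                )
        object.__setattr__(self, "moment_arms", A)
        l0 = np.asarray(self.l0, dtype=float)
        _require_positive("geometry.l0", l0)
        object.__setattr__(self, "l0", l0)
        object.__setattr__(self, "q_ref", np.asarray(self.q_ref, dtype=float))


@dataclass(frozen=True)
class MuscleParameters:
    """Affine activation-dependent visco-elastic muscle law.

    Tension: ``T = max(0, T0 u + (k0 + k1 u) e + (b0 + b1 u) edot)`` where
    ``e`` is the stretch relative to the reference length trajectory.
    Stiffness and viscosity are non-decreasing in activation.
    """

    T0: np.ndarray = field(default_factory=lambda: np.full(N_MUSCLES, 300.0))
    k0: float = 3700.0
    k1: float = 20000.0
    b0: float = 40.0
    b1: float = 160.0

    def __post_init__(self):
        T0 = np.asarray(self.T0, dtype=float)
        if T0.shape != (N_MUSCLES,):
            raise ConfigError("muscle.T0 must have 6 entries")
        _require_positive("muscle.T0", T0)
        object.__setattr__(self, "T0", T0)
        for name in ("k0", "k1", "b0", "b1"):
            _require_nonnegative(f"muscle.{name}", getattr(self, name))

    def stiffness(self, u: np.ndarray) -> np.ndarray:
        """Per-muscle intrinsic stiffness (N/m) at activation ``u``."""
        return self.k0 + self.k1 * np.asarray(u)

    def damping(self, u: np.ndarray) -> np.ndarray:
        """Per-muscle intrinsic viscosity (N s/m) at activation ``u``."""
        return self.b0 + self.b1 * np.asarray(u)


@dataclass(frozen=True)
class NoiseConfig:
    """Signal-dependent motor noise: std proportional to activation."""

    cv: float = 0.03
    cutoff_hz: float = 10.0

    def __post_init__(self):
        _require_nonnegative("noise.cv", self.cv)
        _require_positive("noise.cutoff_hz", self.cutoff_hz)


@dataclass(frozen=True)
class FeedbackConfig:
    """Delayed V-shaped feedback: gains, sliding-error weighting, delay."""

    stretch_slope: float = 30.0
    shortening_slope: float = 15.0
    kappa: float = 0.05
    delay: float = 0.060

    def __post_init__(self):
        _require_positive("feedback.shortening_slope", self.shortening_slope)
        if self.stretch_slope < self.shortening_slope:
            raise ConfigError(
                "feedback.stretch_slope must be >= feedback.shortening_slope "
                "(V-shape is steeper on the stretch side)"
            )
        _require_nonnegative("feedback.kappa", self.kappa)
        _require_nonnegative("feedback.delay", self.delay)
        if self.delay > 0.2:
            raise ConfigError("feedback.delay beyond 0.2 s is outside the model's range")


@dataclass(frozen=True)
class LearningConfig:
    """Between-trial gradient descent on feedback-error cost plus effort.

    ``decay`` defaults to ``rate * effort_weight`` (the uniform winner-take-all
    shrinkage the effort term contributes to the gradient).
    """

    error_weight: float = 1.0
    effort_weight: float = 0.002
    rate: float = 6.0
    decay: float | None = None

    def __post_init__(self):
        for name in ("error_weight", "effort_weight", "rate"):
            _require_nonnegative(f"learning.{name}", getattr(self, name))
        if self.decay is None:
            object.__setattr__(self, "decay", self.rate * self.effort_weight)
        _require_nonnegative("learning.decay", self.decay)


@dataclass(frozen=True)
class RBFConfig:
    """K-means placement and width assignment of the Gaussian network."""

    k_min: int = 3
    k_max: int = 80
    k_init: int = 20
    restart_budget: int = 2000
    lloyd_max_iter: int = 100
    width_scale: float = 2.0
    width_floor: float = 0.15
    improvement_tol: float = 0.05
    isotropic: bool = False

    def __post_init__(self):
        if not (1 <= self.k_min <= self.k_init <= self.k_max):
            raise ConfigError("rbf neuron bounds must satisfy k_min <= k_init <= k_max")
        _require_positive("rbf.restart_budget", self.restart_budget)
        _require_positive("rbf.lloyd_max_iter", self.lloyd_max_iter)
        _require_positive("rbf.width_scale", self.width_scale)
        _require_positive("rbf.width_floor", self.width_floor)
        _require_positive("rbf.improvement_tol", self.improvement_tol)


@dataclass(frozen=True)
class FieldDefaults:
    """Gain parameters of the simulated environments (NF, VF, VFk, DF)."""

    vf_matrix: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, 13.0], [-13.0, 0.0]])
    )
    vfk_gain: float = 30.0
    df_gain: float = 250.0
    barrier_threshold: float = 0.05
    barrier_damping: float = 50.0
    endzone_diameter: float = 0.025

    def __post_init__(self):
        B = np.asarray(self.vf_matrix, dtype=float)
        if B.shape != (2, 2):
            raise ConfigError("fields.vf_matrix must be 2x2")
        object.__setattr__(self, "vf_matrix", B)
        _require_positive("fields.df_gain", self.df_gain)
        _require_positive("fields.barrier_threshold", self.barrier_threshold)
        _require_nonnegative("fields.barrier_damping", self.barrier_damping)
        _require_positive("fields.endzone_diameter", self.endzone_diameter)


@dataclass(frozen=True)
class SimulationConfig:
    dt: float = 0.001
    max_hand_speed: float = 10.0
    baseline_activation: float = 0.02

    def __post_init__(self):
        _require_positive("simulation.dt", self.dt)
        _require_positive("simulation.max_hand_speed", self.max_hand_speed)
        _require_nonnegative(
            "simulation.baseline_activation", self.baseline_activation
        )


@dataclass(frozen=True)
class Config:
    """Top-level configuration tree."""

    arm: ArmParameters = field(default_factory=ArmParameters)
    geometry: MuscleGeometry = field(default_factory=MuscleGeometry)
    muscle: MuscleParameters = field(default_factory=MuscleParameters)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    feedback: FeedbackConfig = field(default_factory=FeedbackConfig)
    learning: LearningConfig = field(default_factory=LearningConfig)
    rbf: RBFConfig = field(default_factory=RBFConfig)
    fields: FieldDefaults = field(default_factory=FieldDefaults)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def replace(self, **sections) -> "Config":
        return dataclasses.replace(self, **sections)

    def to_dict(self) -> dict:
        def convert(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if dataclasses.is_dataclass(obj):
                return {
                    f.name: convert(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            return obj

        return convert(self)


_SECTIONS = {
    "arm": ArmParameters,
    "geometry": MuscleGeometry,
    "muscle": MuscleParameters,
    "noise": NoiseConfig,
    "feedback": FeedbackConfig,
    "learning": LearningConfig,
    "rbf": RBFConfig,
    "fields": FieldDefaults,
    "simulation": SimulationConfig,
}


def _build_section(cls, name: str, mapping: dict):
    if not isinstance(mapping, dict):
        raise ConfigError(f"section '{name}' must be a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in section '{name}': {sorted(unknown)}")
    return cls(**mapping)


def config_from_dict(tree: dict) -> Config:
    """Build a validated :class:`Config` from a nested mapping."""
    unknown = set(tree) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown configuration section(s): {sorted(unknown)}")
    sections = {
        name: _build_section(cls, name, tree.get(name, {}))
        for name, cls in _SECTIONS.items()
    }
    return Config(**sections)


def load_config(path: str | Path) -> Config:
    """Load and validate a YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        tree = yaml.safe_load(fh) or {}
    return config_from_dict(tree)


def default_config() -> Config:
    """The shipped default configuration."""
    text = resources.files("impedadapt.data").joinpath("default.yaml").read_text()
    return config_from_dict(yaml.safe_load(text))
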