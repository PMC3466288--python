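"""Gaussian radial-basis-function feedforward model over the 4-D arm state.

The feedforward command is ``u_ff(x) = max(0, W g(x))`` where ``x = (q, qd)``
is the joint state, ``g`` the vector of Gaussian neuron activations and ``W``
a non-negative 6 x N weight matrix adapted during learning.  Neuron centres
are placed by K-means on states visited during interaction-free movements;
per-neuron widths cover the assigned cluster and are scaled up so adjacent
activation fields overlap.  Centres and widths are then frozen — only the
weights adapt, so generalization across movements happens purely through
overlapping activation fields.

Positions (rad) and velocities (rad/s) are standardized before clustering so
Euclidean distance treats the mixed-unit state space evenly; the same affine
scaling is frozen into the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .config import RBFConfig

__all__ = [
    "RBFNetwork",
    "ClusteringResult",
    "gaussian_activation",
    "kmeans_fit",
    "width_assignment",
    "select_network",
]

STATE_DIM = 4
N_MUSCLES = 6


@dataclass
class ClusteringResult:
    """Outcome of one best-of-restarts K-means fit."""

    labels: np.ndarray
    centroids: np.ndarray
    objective: float          # D: sum of squared distances to assigned centres
    n_iter: int
    K: int


@dataclass
class RBFNetwork:
    """Centres, widths, scaling and weights of the feedforward network."""

    centers: np.ndarray                # (N, 4), standardized units
    widths: np.ndarray                 # (N, 4), standardized units
    x_mean: np.ndarray                 # (4,) standardization offset
    x_scale: np.ndarray                # (4,) standardization scale
    W: np.ndarray = field(default=None)  # (6, N), non-negative

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.widths = np.atleast_2d(np.asarray(self.widths, dtype=float))
        if np.any(self.widths <= 0):
            raise ValueError("widths must be strictly positive")
        if self.W is None:
            self.W = np.zeros((N_MUSCLES, self.n_neurons))
        self.W = np.asarray(self.W, dtype=float)
        if np.any(self.W < 0):
            raise ValueError("weights must be non-negative")

    @property
    def n_neurons(self) -> int:
        return self.centers.shape[0]

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.x_mean) / self.x_scale

    def activations(self, x: np.ndarray) -> np.ndarray:
        """Neuron activations ``g(x)`` in (0, 1] for raw state ``x``."""
        z = self.standardize(x)
        d2 = np.sum(((z - self.centers) / self.widths) ** 2, axis=1)
        return np.exp(-0.5 * d2)

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Feedforward command ``max(0, W g(x))``."""
        return np.maximum(self.W @ self.activations(x), 0.0)

    def phi_matrix(self, x: np.ndarray) -> np.ndarray:
        """The linear-in-parameters basis matrix at state ``x``.

        With the weight matrix flattened row-wise into a parameter vector
        ``w``, the network output is exactly ``Phi(x) w`` with
        ``Phi = kron(I_6, g(x)^T)`` — the structural identity tying the
        network to the generic learning law.
        """
        return np.kron(np.eye(N_MUSCLES), self.activations(x)[None, :])

    @property
    def weights_flat(self) -> np.ndarray:
        return self.W.reshape(-1)

    def to_dict(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "widths": self.widths.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "W": self.W.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RBFNetwork":
        return cls(
            np.asarray(d["centers"], float),
            np.asarray(d["widths"], float),
            np.asarray(d["x_mean"], float),
            np.asarray(d["x_scale"], float),
            np.asarray(d["W"], float),
        )


def gaussian_activation(x, center, width) -> float:
    """Single-neuron Gaussian activation in (0, 1].

    Equals 1 exactly at the centre and decreases strictly with scaled
    distance; ``width`` may be scalar (isotropic) or per-dimension.
    """
    x = np.asarray(x, dtype=float)
    center = np.asarray(center, dtype=float)
    width = np.asarray(width, dtype=float)
    if np.any(width <= 0):
        raise ValueError("width must be strictly positive")
    return float(np.exp(-0.5 * np.sum(((x - center) / width) ** 2)))


def kmeans_fit(
    states: np.ndarray,
    K: int,
    n_restarts: int = 10,
    seed: int | None = None,
    max_iter: int = 100,
) -> ClusteringResult:
    """Best-of-restarts Lloyd K-means on the given states.

    Minimizes the sum of squared distances to the assigned centres; the
    restart with minimal objective wins.  Deterministic for a given seed.
    Empty clusters are re-seeded internally from distant points.
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if K > np.unique(states, axis=0).shape[0]:
        raise ValueError("K exceeds the number of distinct states")
    km = KMeans(
        n_clusters=K,
        n_init=max(1, int(n_restarts)),
        max_iter=int(max_iter),
        algorithm="lloyd",
        random_state=None if seed is None else int(seed) % (2**32),
    ).fit(states)
    return ClusteringResult(
        labels=km.labels_.copy(),
        centroids=km.cluster_centers_.copy(),
        objective=float(km.inertia_),
        n_iter=int(km.n_iter_),
        K=K,
    )


def width_assignment(
    clustering: ClusteringResult,
    states: np.ndarray,
    scale_factor: float,
    width_floor: float = 0.15,
    isotropic: bool = False,
) -> np.ndarray:
    """Per-neuron activation-field widths covering the assigned data.

    The base width of a neuron is the largest distance (per dimension, or
    Euclidean if isotropic) from its centroid to any member of its cluster —
    "include all data within the cluster" — multiplied by ``scale_factor``
    so the Gaussians of adjacent neurons overlap.  Singleton clusters fall
    back to the floor width.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    states = np.atleast_2d(np.asarray(states, dtype=float))
    K, dim = clustering.centroids.shape
    widths = np.empty((K, dim))
    for j in range(K):
        members = states[clustering.labels == j]
        diff = np.abs(members - clustering.centroids[j])
        if isotropic:
            base = np.full(dim, np.max(np.linalg.norm(diff, axis=1)))
        else:
            base = diff.max(axis=0)
        widths[j] = np.maximum(base * scale_factor, width_floor)
    return widths


def select_network(
    states: np.ndarray,
    cfg: RBFConfig,
    seed: int | None = None,
) -> RBFNetwork:
    """Cluster the state data and build an unweighted network.

    The neuron count is searched within ``[k_min, k_max]`` starting from
    ``k_init`` by diminishing returns on the clustering objective: the
    count grows while adding a neuron still shrinks ``D`` by at least the
    relative ``improvement_tol``, and shrinks while removing one loses
    less than that.  (For states sampled along movement trajectories the
    relative gain per added neuron decays like ``2/K``, so the criterion
    is insensitive to the number and length of the movements.)  The total
    restart budget is split across the counts examined.  Weights start at
    zero; widths follow :func:`width_assignment`.
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if states.shape[0] == 0:
        raise ValueError("no states to cluster")
    n_distinct = np.unique(states, axis=0).shape[0]
    if n_distinct < cfg.k_min:
        raise ValueError("fewer distinct states than the minimum neuron count")

    x_mean = states.mean(axis=0)
    x_scale = states.std(axis=0)
    x_scale[x_scale < 1e-12] = 1.0
    z = (states - x_mean) / x_scale

    per_k = max(1, cfg.restart_budget // (cfg.k_max - cfg.k_min + 1))
    budget = cfg.restart_budget
    rng = np.random.default_rng(seed)

    def fit(K):
        nonlocal budget
        n_init = min(per_k, max(1, budget))
        budget -= n_init
        return kmeans_fit(
            z, K, n_restarts=n_init,
            seed=int(rng.integers(2**31)), max_iter=cfg.lloyd_max_iter,
        )

    K = min(cfg.k_init, n_distinct)
    best = fit(K)
    k_hi = min(cfg.k_max, n_distinct)
    tol = cfg.improvement_tol
    cand = fit(K + 1) if K < k_hi else None
    if cand is not None and (best.objective - cand.objective) > tol * best.objective:
        # adding neurons still pays off: grow
        while K < k_hi and budget > 0:
            if (best.objective - cand.objective) <= tol * best.objective:
                break
            K += 1
            best = cand
            cand = fit(K + 1) if K < k_hi else None
            if cand is None:
                break
    else:
        # removing neurons costs little: shrink
        while K > cfg.k_min and budget > 0:
            down = fit(K - 1)
            if (down.objective - best.objective) > tol * down.objective:
                break
            K -= 1
            best = down

    widths = width_assignment(
        best, z, cfg.width_scale, cfg.width_floor, cfg.isotropic
    )
    return RBFNetwork(best.centroids, widths, x_mean, x_scale)
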