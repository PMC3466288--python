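"""Gaussian basis, K-means placement, width assignment, size selection."""

import dataclasses
import itertools

import numpy as np
import pytest

import impedadapt as ia
from impedadapt.rbf import (
    RBFNetwork,
    gaussian_activation,
    kmeans_fit,
    select_network,
    width_assignment,
)


class TestGaussianActivation:
    def test_unity_at_center(self, rng):
        c = rng.normal(size=4)
        assert gaussian_activation(c, c, 0.5) == 1.0

    def test_one_width_away_is_exp_minus_half(self):
        c = np.zeros(4)
        x = np.array([0.7, 0, 0, 0])
        assert np.isclose(gaussian_activation(x, c, 0.7), np.exp(-0.5))

    def test_strictly_decreasing_with_distance(self):
        c = np.zeros(4)
        g1 = gaussian_activation([0.5, 0, 0, 0], c, 1.0)
        g2 = gaussian_activation([1.0, 0, 0, 0], c, 1.0)
        assert 0 < g2 < g1 <= 1

    def test_positive_width_required(self):
        with pytest.raises(ValueError):
            gaussian_activation(np.zeros(4), np.zeros(4), 0.0)


class TestEvaluate:
    def test_zero_weights_zero_output(self, small_net, rng):
        x = rng.normal(size=4)
        net = RBFNetwork.from_dict(small_net.to_dict())
        net.W[:] = 0.0
        assert np.allclose(net.evaluate(x), 0.0)

    def test_single_neuron_output_scales_with_activation(self):
        net = RBFNetwork(
            centers=np.zeros((1, 4)), widths=np.ones((1, 4)),
            x_mean=np.zeros(4), x_scale=np.ones(4),
            W=np.arange(6, dtype=float).reshape(6, 1),
        )
        x = np.array([1.0, 0, 0, 0])
        g = net.activations(x)[0]
        assert np.allclose(net.evaluate(x), np.arange(6) * g)

    def test_linear_primitive_identity(self, small_net, rng):
        # network evaluation == Phi(x) @ w with Phi = kron(I, g^T); the
        # identity is exact up to float summation order
        net = RBFNetwork.from_dict(small_net.to_dict())
        net.W = rng.uniform(0, 1, net.W.shape)
        for _ in range(100):
            x = rng.normal(size=4)
            direct = net.evaluate(x)
            via_phi = np.maximum(net.phi_matrix(x) @ net.weights_flat, 0.0)
            assert np.allclose(direct, via_phi, rtol=1e-12, atol=0.0)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            RBFNetwork(
                centers=np.zeros((1, 4)), widths=np.ones((1, 4)),
                x_mean=np.zeros(4), x_scale=np.ones(4),
                W=-np.ones((6, 1)),
            )


class TestKMeans:
    def test_single_cluster_of_identical_points(self):
        pts = np.tile([1.0, 2.0, 0.0, 0.0], (5, 1))
        res = kmeans_fit(pts, 1, n_restarts=2, seed=0)
        assert np.allclose(res.centroids[0], pts[0])
        assert res.objective == 0.0

    def test_two_separated_pairs_found_by_brute_force(self):
        pts = np.array(
            [[0, 0, 0, 0], [0.2, 0, 0, 0], [5, 5, 0, 0], [5.2, 5, 0, 0]],
            dtype=float,
        )
        res = kmeans_fit(pts, 2, n_restarts=10, seed=0)
        # brute force over all 2-partitions
        best = np.inf
        for mask in itertools.product([0, 1], repeat=4):
            mask = np.array(mask)
            if mask.min() == mask.max():
                continue
            d = 0.0
            for g in (0, 1):
                sub = pts[mask == g]
                d += np.sum((sub - sub.mean(axis=0)) ** 2)
            best = min(best, d)
        assert np.isclose(res.objective, best)

    def test_objective_beats_random_placements(self, rng):
        pts = rng.normal(size=(60, 4))
        res = kmeans_fit(pts, 5, n_restarts=10, seed=0)
        for _ in range(1000):
            cand = pts[rng.choice(60, 5, replace=False)]
            d2 = ((pts[:, None, :] - cand[None]) ** 2).sum(axis=2).min(axis=1)
            assert res.objective <= d2.sum() + 1e-9

    def test_more_clusters_than_distinct_points_rejected(self):
        pts = np.tile([0.0, 0, 0, 0], (5, 1))
        with pytest.raises(ValueError):
            kmeans_fit(pts, 2)


class TestWidthAssignment:
    def test_singleton_cluster_gets_floor_width(self):
        pts = np.array([[0, 0, 0, 0], [1, 0, 0, 0], [1.1, 0, 0, 0]], float)
        res = kmeans_fit(pts, 2, n_restarts=5, seed=0)
        w = width_assignment(res, pts, scale_factor=2.0, width_floor=0.15)
        sizes = np.bincount(res.labels)
        singleton = int(np.argmin(sizes))
        assert np.allclose(w[singleton], 0.15)

    def test_widths_scale_homogeneously(self, rng):
        pts = rng.normal(size=(40, 4))
        res = kmeans_fit(pts, 4, n_restarts=5, seed=0)
        w1 = width_assignment(res, pts, 1.0, width_floor=1e-9)
        w2 = width_assignment(res, pts, 2.0, width_floor=1e-9)
        assert np.allclose(w2, 2 * w1)

    def test_positive_scale_required(self, rng):
        pts = rng.normal(size=(10, 4))
        res = kmeans_fit(pts, 2, n_restarts=2, seed=0)
        with pytest.raises(ValueError):
            width_assignment(res, pts, 0.0)


class TestSelectNetwork:
    def test_forced_neuron_count(self, cfg, rng):
        pts = rng.normal(size=(100, 4))
        rbf = dataclasses.replace(cfg.rbf, k_min=5, k_max=5, k_init=5)
        net = select_network(pts, rbf, seed=0)
        assert net.n_neurons == 5

    def test_two_reach_paths_are_covered_with_overlap(self, cfg):
        # states from two straight movements 35 degrees apart: every
        # training state activates its own neighbourhood, and at least two
        # neurons respond above 0.05 (adjacent fields overlap)
        from impedadapt.experiments import (
            DF_DURATION, DF_HOLD, DF_START, df_goals,
        )
        from impedadapt.controller import reach_plan
        from impedadapt.experiments import states_from_plans

        plans = [
            reach_plan(DF_START, g, DF_DURATION, cfg, hold=DF_HOLD)
            for g in df_goals()
        ]
        states = states_from_plans(plans)
        net = select_network(states, cfg.rbf, seed=0)
        z = (states - net.x_mean) / net.x_scale
        for x in states[::7]:
            g = net.activations(x)
            assert np.sort(g)[-2] > 0.05
        # every state within 2 widths of some centre (scaled distance)
        for x in z[::7]:
            d = np.sqrt(
                (((x - net.centers) / net.widths) ** 2).sum(axis=1)
            ).min()
            assert d < 2.0

    def test_too_few_distinct_states_rejected(self, cfg):
        pts = np.tile([0.0, 0, 0, 0], (10, 1))
        with pytest.raises(ValueError):
            select_network(pts, cfg.rbf, seed=0)

    def test_selection_deterministic_given_seed(self, cfg, rng):
        pts = rng.normal(size=(200, 4))
        n1 = select_network(pts, cfg.rbf, seed=42)
        n2 = select_network(pts, cfg.rbf, seed=42)
        assert n1.n_neurons == n2.n_neurons
        assert np.array_equal(n1.centers, n2.centers)

    def test_serialization_roundtrip(self, small_net):
        net2 = RBFNetwork.from_dict(small_net.to_dict())
        assert np.array_equal(net2.centers, small_net.centers)
        assert np.array_equal(net2.widths, small_net.widths)
        assert np.array_equal(net2.W, small_net.W)


class TestGeneralizationLocality:
    def test_output_vanishes_far_from_trained_region(self, small_net, rng):
        net = RBFNetwork.from_dict(small_net.to_dict())
        net.W = rng.uniform(0.5, 1.0, net.W.shape)
        far = net.x_mean + 30.0 * net.x_scale
        assert np.all(net.evaluate(far) < 1e-6)
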