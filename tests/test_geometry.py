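"""Arbor-network geometry: uniform filling, overlap graph, CACs, isolation."""

import numpy as np
import pytest

from striatum.geometry import (
    ArborNetwork,
    EllipsoidStriatum,
    NetworkConfig,
    contiguous_arbor_classes,
    generate_striatum,
    isolated_fraction,
    most_isolated_points,
    nearest_arbor_distances,
    overlap_counts,
)

from conftest import scaled_config, toy_network


class TestEllipsoid:
    def test_volume_and_containment(self):
        ell = EllipsoidStriatum((14.0, 9.0, 9.0))
        assert ell.volume == pytest.approx(4.0 / 3.0 * np.pi * 14 * 9 * 9)
        assert ell.contains([0.0, 0.0, 0.0])
        assert ell.contains([13.99, 0.0, 0.0])
        assert not ell.contains([0.0, 9.01, 0.0])

    def test_sampling_uniform_inside(self):
        ell = EllipsoidStriatum((2.0, 1.0, 1.0))
        pts = ell.sample_points(5000, np.random.default_rng(0))
        assert ell.contains(pts).all()
        # each coordinate has symmetric mean
        assert np.abs(pts.mean(axis=0)).max() < 0.05

    @pytest.mark.parametrize("axes", [(0.0, 1, 1), (-1, 1, 1)])
    def test_invalid_axes(self, axes):
        with pytest.raises(ValueError):
            EllipsoidStriatum(axes)


class TestGenerate:
    def test_deterministic_given_seed(self):
        a = generate_striatum(scaled_config(500, seed=9))
        b = generate_striatum(scaled_config(500, seed=9))
        np.testing.assert_array_equal(a.centers, b.centers)

    def test_empty_network(self):
        net = generate_striatum(NetworkConfig(n_neurons=0))
        assert net.n_arbors == 0
        part = contiguous_arbor_classes(net)
        assert part.n_classes == 0
        assert isolated_fraction(net, n_points=100) == 1.0

    def test_lognormal_radii_have_requested_median(self):
        cfg = scaled_config(4000, seed=2, radius_spread=0.3)
        net = generate_striatum(cfg)
        assert np.median(net.radii) == pytest.approx(0.5, rel=0.05)
        assert net.radii.std() > 0


class TestOverlap:
    def test_two_arbors_within_threshold(self):
        net = toy_network([[0, 0, 0], [0.4, 0, 0]])
        np.testing.assert_array_equal(overlap_counts(net), [1, 1])

    def test_two_arbors_beyond_threshold(self):
        net = toy_network([[0, 0, 0], [0.6, 0, 0]])
        np.testing.assert_array_equal(overlap_counts(net), [0, 0])

    def test_threshold_is_strict(self):
        net = toy_network([[0, 0, 0], [0.5, 0, 0]])
        np.testing.assert_array_equal(overlap_counts(net), [0, 0])

    def test_poisson_like_counts_at_default_density(self, net10k):
        # boundary arbors see a truncated neighborhood, so the Poisson law
        # holds for arbors whose 0.5 mm ball lies inside the ellipsoid
        counts = overlap_counts(net10k)
        axes = np.asarray(net10k.config.ellipsoid.semi_axes)
        interior = np.sum((net10k.live_centers / (axes - 0.5)) ** 2, axis=1) <= 1
        mean, var = counts[interior].mean(), counts[interior].var()
        assert abs(mean - var) / mean < 0.1
        expected = 10_000 * (4 / 3 * np.pi * 0.5**3) / net10k.config.ellipsoid.volume
        assert mean == pytest.approx(expected, rel=0.05)

    def test_density_linearity(self):
        # halving the count in the same volume halves the mean overlap
        cfg = scaled_config(10_000, seed=5)
        half = NetworkConfig(n_neurons=5_000, ellipsoid=cfg.ellipsoid, seed=6)
        m_full = overlap_counts(generate_striatum(cfg)).mean()
        m_half = overlap_counts(generate_striatum(half)).mean()
        assert m_half == pytest.approx(m_full / 2, rel=0.1)


def _bfs_components(centers, threshold):
    """O(n^2) breadth-first-search oracle for connected components."""
    n = len(centers)
    d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
    adj = (d < threshold) & ~np.eye(n, dtype=bool)
    labels = np.full(n, -1)
    cur = 0
    for start in range(n):
        if labels[start] >= 0:
            continue
        stack = [start]
        labels[start] = cur
        while stack:
            i = stack.pop()
            for j in np.flatnonzero(adj[i]):
                if labels[j] < 0:
                    labels[j] = cur
                    stack.append(j)
        cur += 1
    return labels


class TestCAC:
    def test_three_collinear_connected(self):
        net = toy_network([[0, 0, 0], [0.4, 0, 0], [0.8, 0, 0]])
        part = contiguous_arbor_classes(net)
        assert part.n_classes == 1
        assert list(part.class_sizes) == [3]

    def test_three_collinear_disconnected(self):
        net = toy_network([[0, 0, 0], [0.6, 0, 0], [1.2, 0, 0]])
        part = contiguous_arbor_classes(net)
        assert part.n_classes == 3
        assert sorted(part.class_sizes) == [1, 1, 1]

    def test_matches_bruteforce_bfs_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(3):
            centers = rng.uniform(0, 3.0, size=(200, 3))
            net = toy_network(centers)
            part = contiguous_arbor_classes(net)
            oracle = _bfs_components(centers, 0.5)
            # same partition up to label renaming
            assert part.n_classes == oracle.max() + 1
            for lab in range(part.n_classes):
                members = np.flatnonzero(part.labels == lab)
                assert len(set(oracle[members])) == 1

    def test_partition_invariant_under_relabeling(self):
        rng = np.random.default_rng(7)
        centers = rng.uniform(0, 2.0, size=(150, 3))
        perm = rng.permutation(150)
        a = contiguous_arbor_classes(toy_network(centers))
        b = contiguous_arbor_classes(toy_network(centers[perm]))
        assert sorted(a.class_sizes) == sorted(b.class_sizes)

    def test_dead_arbors_excluded(self):
        net = toy_network([[0, 0, 0], [0.4, 0, 0], [0.8, 0, 0]])
        net.alive[1] = False
        part = contiguous_arbor_classes(net)
        assert part.labels[1] == -1
        assert part.n_classes == 2


class TestNearestDistances:
    def test_point_at_center_and_unit_offset(self):
        net = toy_network([[0, 0, 0]])
        d = nearest_arbor_distances(net, [[0, 0, 0], [1.0, 0, 0]])
        np.testing.assert_allclose(d, [0.0, 1.0])

    def test_empty_network_gives_infinity(self):
        net = toy_network([[0, 0, 0]])
        net.alive[0] = False
        assert np.isinf(nearest_arbor_distances(net, [[0, 0, 0]])).all()

    def test_matches_bruteforce_on_500_arbors(self):
        rng = np.random.default_rng(3)
        centers = rng.uniform(-2, 2, size=(500, 3))
        pts = rng.uniform(-2, 2, size=(200, 3))
        net = toy_network(centers)
        d = nearest_arbor_distances(net, pts)
        brute = np.min(
            np.linalg.norm(pts[:, None] - centers[None, :], axis=-1), axis=1
        )
        np.testing.assert_allclose(d, brute)


class TestIsolatedFraction:
    def test_empty_network_fully_isolated(self):
        net = generate_striatum(NetworkConfig(n_neurons=0))
        assert isolated_fraction(net, n_points=500) == 1.0

    def test_zero_points_rejected(self, net10k):
        with pytest.raises(ValueError):
            isolated_fraction(net10k, n_points=0)

    def test_monotone_in_live_arbors(self, net10k):
        # removing arbors can only create isolation, never remove it
        rng = np.random.default_rng(0)
        fractions = []
        net = net10k.copy()
        for keep in (1.0, 0.3, 0.05, 0.01):
            alive = np.zeros(net.n_arbors, dtype=bool)
            alive[: int(keep * net.n_arbors)] = True
            fractions.append(isolated_fraction(net.with_alive(alive), seed=1))
        assert all(a <= b for a, b in zip(fractions, fractions[1:]))

    def test_surface_criterion(self):
        # point 0.55 mm from a 0.5 mm arbor center is 0.05 mm from its
        # surface: not isolated at 0.1 mm margin, isolated at 0.01
        net = toy_network([[0, 0, 0]], radius=0.5)
        d = nearest_arbor_distances(net, [[0.55, 0, 0]])[0]
        assert d - 0.5 == pytest.approx(0.05)

    def test_heterogeneous_radii_surface_distances(self):
        from striatum.geometry import _nearest_surface_distances

        rng = np.random.default_rng(5)
        centers = rng.uniform(-2, 2, size=(300, 3))
        radii = rng.uniform(0.2, 0.8, size=300)
        cfg = NetworkConfig(n_neurons=300)
        net = ArborNetwork(cfg, centers, radii)
        pts = rng.uniform(-2, 2, size=(100, 3))
        got = _nearest_surface_distances(net, pts)
        brute = np.min(
            np.linalg.norm(pts[:, None] - centers[None, :], axis=-1) - radii[None, :],
            axis=1,
        )
        np.testing.assert_allclose(got, brute)


class TestMostIsolated:
    def test_two_arbor_symmetry(self):
        # most isolated candidates lie on the boundary or midway; either way
        # the reported distance must beat the midpoint distance
        net = toy_network([[-1, 0, 0], [1, 0, 0]])
        res = most_isolated_points(net, mc_points=20_000, seed=0)
        assert res.method == "monte_carlo"  # < 4 arbors
        assert res.distances[0] >= 1.0 - 0.05

    def test_matches_dense_monte_carlo(self):
        net = generate_striatum(scaled_config(500, seed=8))
        res = most_isolated_points(net, seed=1)
        assert res.method == "voronoi"
        rng = np.random.default_rng(2)
        pts = net.config.ellipsoid.sample_points(200_000, rng)
        mc_max = nearest_arbor_distances(net, pts).max()
        assert res.distances[0] >= mc_max * 0.95

    def test_sorted_descending(self, net10k):
        res = most_isolated_points(net10k, top_k=50, seed=0)
        assert np.all(np.diff(res.distances) <= 1e-12)
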