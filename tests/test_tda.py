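"""Subsampling, alpha persistence, heat kernel and Gram assembly.

The persistence implementation is checked three ways: analytic cases
(triangle, circle), an independent brute-force oracle (exhaustive alpha
filtration + dense boundary-matrix reduction) on random small clouds,
and structural invariants (rigid motion, scaling, planted loops).
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from _oracles import brute_alpha_diagram_degree1, numeric_heat_kernel
from cnscensus.core import (DegenerateInputError, InsufficientDataError,
                            ParameterError, PersistenceDiagram, PointCloud,
                            Sex)
from cnscensus.tda import (alpha_persistence_degree1, gram_matrix,
                           heat_kernel, rbf_feature_gram, subsample_cloud,
                           to_radius_units, truncate_diagram)


def _cloud(points, animal="a"):
    return PointCloud(animal, "sim", Sex.UNKNOWN, points)


class TestSubsample:
    def test_full_size_subsample_equals_parent(self, small_cloud):
        sset = subsample_cloud(small_cloud, small_cloud.n_points, 3, seed=1)
        for sub in sset.clouds:
            np.testing.assert_array_equal(
                np.sort(sub.points, axis=0),
                np.sort(small_cloud.points, axis=0))

    def test_deterministic_and_without_replacement(self, small_cloud):
        a = subsample_cloud(small_cloud, 10, 5, seed=2)
        b = subsample_cloud(small_cloud, 10, 5, seed=2)
        for x, y in zip(a.clouds, b.clouds):
            np.testing.assert_array_equal(x.points, y.points)
        for sub in a.clouds:
            assert np.unique(sub.points, axis=0).shape[0] == 10

    def test_oversized_request_raises(self, small_cloud):
        with pytest.raises(InsufficientDataError):
            subsample_cloud(small_cloud, small_cloud.n_points + 1, 1, seed=0)

    def test_repeats_times_parents_bookkeeping(self, small_cloud):
        sset = subsample_cloud(small_cloud, 5, 100, seed=0)
        assert len(sset.clouds) == 100
        assert sset.parent_animal_id == small_cloud.animal_id


class TestAlphaPersistence:
    def test_two_points_empty_diagram(self):
        assert len(alpha_persistence_degree1(_cloud([[0, 0, 0], [1, 0, 0]]))) == 0

    def test_equilateral_triangle(self, rng):
        tri = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        d = alpha_persistence_degree1(_cloud(tri + rng.normal(0, 1e-7,
                                                              tri.shape)))
        assert len(d) == 1
        # birth = (side/2)^2, death = circumradius^2 = 1/3.
        np.testing.assert_allclose(d.points[0], [0.25, 1 / 3], atol=1e-6)

    def test_circle_20_points(self, rng):
        th = np.linspace(0, 2 * np.pi, 20, endpoint=False)
        pts = np.column_stack([np.cos(th), np.sin(th), np.zeros(20)])
        d = alpha_persistence_degree1(_cloud(pts + rng.normal(0, 1e-8,
                                                              pts.shape)))
        dominant = d.points[np.argmax(d.persistence)]
        assert dominant[1] == pytest.approx(1.0, abs=1e-6)
        assert dominant[0] == pytest.approx(np.sin(np.pi / 20) ** 2, abs=1e-6)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_oracle(self, trial):
        # Pairs below the 1e-9 comparison tolerance are dropped on both
        # sides: the oracle computes each simplex value independently, so
        # simplices that enter simultaneously can acquire ~1e-12 slivers.
        rng = np.random.default_rng(1000 + trial)
        pts = rng.uniform(0, 2, (int(rng.integers(5, 9)), 3))
        mine = alpha_persistence_degree1(_cloud(pts),
                                         min_persistence=1e-9).points
        oracle = brute_alpha_diagram_degree1(pts, min_persistence=1e-9)
        assert mine.shape == oracle.shape
        if mine.size:
            np.testing.assert_allclose(mine, oracle, atol=1e-9)

    def test_rigid_motion_invariance_and_scaling(self, rng):
        pts = rng.uniform(0, 4, (60, 3))
        base = alpha_persistence_degree1(_cloud(pts)).points
        rot = Rotation.from_rotvec([1.0, 0.2, -0.5]).as_matrix()
        moved = alpha_persistence_degree1(
            _cloud(pts @ rot.T + np.array([5.0, 1.0, -2.0]))).points
        scaled = alpha_persistence_degree1(_cloud(3.0 * pts)).points
        np.testing.assert_allclose(moved, base, atol=1e-8)
        np.testing.assert_allclose(scaled, 9.0 * base, rtol=1e-8)

    def test_collinear_points_degenerate(self):
        pts = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateInputError):
            alpha_persistence_degree1(_cloud(pts))

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_circle_death_near_radius_squared(self, seed):
        """A jittered circle of radius R among sparse background (kept
        clear of the disk it spans, so the fill-in scale is set by the
        loop, not by background spacing) yields a low-birth loop whose
        death is within 15% of R^2."""
        rng = np.random.default_rng(seed)
        radius = 10.0
        th = (np.linspace(0, 2 * np.pi, 40, endpoint=False)
              + rng.uniform(0, 0.05, 40))
        ring = np.column_stack([radius * np.cos(th), radius * np.sin(th),
                                np.zeros(40)]) + rng.normal(0, 0.2, (40, 3))
        background = rng.uniform(-40, 40, (200, 3))
        background = background[
            np.linalg.norm(background, axis=1) > 1.2 * radius][:60]
        d = alpha_persistence_degree1(_cloud(np.vstack([ring, background])))
        low_birth = d.points[d.points[:, 0] < 4.0]
        dominant = low_birth[np.argmax(low_birth[:, 1] - low_birth[:, 0])]
        assert dominant[1] == pytest.approx(radius**2, rel=0.15)

    def test_radius_units_conversion(self, rng):
        d = alpha_persistence_degree1(_cloud(rng.uniform(0, 3, (30, 3))))
        np.testing.assert_allclose(to_radius_units(d).points,
                                   np.sqrt(d.points))


class TestHeatKernel:
    def test_empty_diagram_gives_zero(self):
        f = PersistenceDiagram(1, [])
        g = PersistenceDiagram(1, [[0, 1]])
        assert heat_kernel(f, g, 0.01) == 0.0

    def test_single_point_self_similarity_closed_form(self):
        d = PersistenceDiagram(1, [[0.0, 1.0]])
        expected = (1 - np.exp(-2 / 0.08)) / (8 * np.pi * 0.01)
        assert heat_kernel(d, d, 0.01) == pytest.approx(expected, abs=1e-12)
        assert heat_kernel(d, d, 0.01) == pytest.approx(3.97887, abs=1e-4)

    def test_far_separated_diagrams_vanish(self):
        f = PersistenceDiagram(1, [[0, 1]])
        g = PersistenceDiagram(1, [[100, 101]])
        assert heat_kernel(f, g, 0.01) < 1e-300

    def test_matches_numeric_heat_solution_inner_product(self):
        f = np.array([[0.3, 1.1], [0.2, 0.9]])
        g = np.array([[0.25, 1.0], [0.6, 1.4]])
        closed = heat_kernel(PersistenceDiagram(1, f),
                             PersistenceDiagram(1, g), 0.05)
        numeric = numeric_heat_kernel(f, g, 0.05)
        assert closed == pytest.approx(numeric, rel=1e-6)

    def test_cauchy_schwarz(self, rng):
        for _ in range(10):
            f = PersistenceDiagram(1, np.sort(rng.uniform(0, 2, (5, 2)), axis=1))
            g = PersistenceDiagram(1, np.sort(rng.uniform(0, 2, (7, 2)), axis=1))
            kfg = heat_kernel(f, g, 0.05)
            assert kfg**2 <= (heat_kernel(f, f, 0.05)
                              * heat_kernel(g, g, 0.05)) * (1 + 1e-12)

    def test_invalid_sigma(self):
        d = PersistenceDiagram(1, [[0, 1]])
        with pytest.raises(ParameterError):
            heat_kernel(d, d, 0.0)


def _random_diagrams(rng, n=10):
    out = []
    for _ in range(n):
        b = rng.uniform(0, 2, int(rng.integers(2, 9)))
        out.append(PersistenceDiagram(1, np.column_stack(
            [b, b + rng.uniform(0, 2, b.size)])))
    return out


class TestGram:
    def test_matches_pairwise_heat_kernel(self, rng):
        diags = _random_diagrams(rng)
        g = gram_matrix(diags, [f"a{i}" for i in range(10)], sigma=0.05)
        ref = np.array([[heat_kernel(x, y, 0.05) for y in diags]
                        for x in diags])
        np.testing.assert_allclose(g.matrix, ref, atol=1e-12)

    def test_positive_semidefinite(self, rng):
        g = gram_matrix(_random_diagrams(rng), ["x"] * 10, sigma=0.01)
        ev = np.linalg.eigvalsh(g.matrix)
        assert ev.min() >= -1e-8 * ev.max()

    def test_duplicated_diagram_gives_equal_rows(self, rng):
        d = _random_diagrams(rng, 1)[0]
        g = gram_matrix([d, d, d], ["a", "b", "c"], sigma=0.05)
        assert np.allclose(g.matrix, g.matrix[0, 0])

    def test_truncation_keeps_strongest_pairs(self):
        d = PersistenceDiagram(1, [[0, 0.1], [0, 2.0], [0, 0.5], [1, 1.01]])
        t = truncate_diagram(d, 2)
        np.testing.assert_allclose(t.points, [[0, 2.0], [0, 0.5]])


class TestRbfGram:
    def test_identical_rows_give_unit_entry(self):
        g = rbf_feature_gram(np.array([[1.0, 2.0], [1.0, 2.0]]), 10.0,
                             ["a", "b"])
        np.testing.assert_allclose(g.matrix, 1.0)

    def test_closed_form_at_bandwidth_distance(self):
        feats = np.array([[0.0], [1e5]])
        g = rbf_feature_gram(feats, 1e5, ["a", "b"])
        assert g.matrix[0, 1] == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_large_bandwidth_limit_all_ones(self, rng):
        feats = rng.normal(size=(5, 3))
        g = rbf_feature_gram(feats, 1e12, ["x"] * 5)
        np.testing.assert_allclose(g.matrix, 1.0, atol=1e-9)

    def test_gamma_convention(self):
        feats = np.array([[0.0], [10.0]])
        g = rbf_feature_gram(feats, 100.0, ["a", "b"], convention="gamma")
        assert g.matrix[0, 1] == pytest.approx(np.exp(-1.0), rel=1e-12)
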