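import itertools

import numpy as np
import pytest

from foci.cell_geometry import (
    EllipsoidMeasure,
    FittedSphere,
    ellipsoid_volume,
    fit_sphere,
    relative_periphery_distance,
    volume_ratio,
)
from foci.exceptions import ValidationError
from foci.synthetic_data import simulate_aggregate_positions, simulate_cell
from foci.trajectory_io import CellEdgeSet

AXIS_POINTS = np.array(
    [[2, 0, 0], [-2, 0, 0], [0, 2, 0], [0, -2, 0], [0, 0, 2], [0, 0, -2]], float
)


class TestEllipsoidVolume:
    def test_unit_sphere(self):
        """Full lengths 2,2,2 μm are semi-axes 1,1,1: V = 4π/3."""
        assert ellipsoid_volume(2, 2, 2) == pytest.approx(4 * np.pi / 3)

    def test_general_ellipsoid(self):
        assert ellipsoid_volume(2, 4, 6) == pytest.approx(8 * np.pi)

    @pytest.mark.parametrize("bad", [(0, 1, 1), (1, -2, 1), (1, 1, float("nan"))])
    def test_nonpositive_length_is_error_not_zero(self, bad):
        with pytest.raises(ValidationError):
            ellipsoid_volume(*bad)

    def test_permutation_invariance_and_monotonicity(self):
        base = ellipsoid_volume(1.0, 2.0, 3.0)
        for perm in itertools.permutations([1.0, 2.0, 3.0]):
            assert ellipsoid_volume(*perm) == pytest.approx(base)
        assert ellipsoid_volume(1.1, 2.0, 3.0) > base


class TestVolumeRatio:
    def test_equal_volumes_give_one(self):
        m = EllipsoidMeasure([2.0, 2.0, 2.0])
        assert volume_ratio(m, m) == pytest.approx(1.0)

    def test_tenth_ratio(self):
        focus = EllipsoidMeasure([2.0, 2.0, 2.0])  # 4pi/3
        cell = EllipsoidMeasure([2.0, 4.0, 10.0])  # 40pi/3
        assert volume_ratio(focus, cell) == pytest.approx(0.1)

    def test_focus_larger_than_cell_warns(self, caplog):
        big = EllipsoidMeasure([4.0, 4.0, 4.0])
        small = EllipsoidMeasure([2.0, 2.0, 2.0])
        with caplog.at_level("WARNING"):
            ratio = volume_ratio(big, small)
        assert ratio == pytest.approx(8.0)
        assert "measurement error" in caplog.text


class TestFitSphere:
    def test_exact_axis_points(self):
        sphere = fit_sphere(CellEdgeSet("c1", edge_points=AXIS_POINTS))
        np.testing.assert_allclose(sphere.center, 0.0, atol=1e-9)
        assert sphere.radius == pytest.approx(2.0, abs=1e-9)
        assert sphere.rms_residual == pytest.approx(0.0, abs=1e-9)
        assert sphere.method == "least_squares_edges"

    def test_exact_offset_sphere(self):
        sphere = fit_sphere(CellEdgeSet("c1", edge_points=AXIS_POINTS + [1.0, -2.0, 3.0]))
        np.testing.assert_allclose(sphere.center, [1.0, -2.0, 3.0], atol=1e-9)
        assert sphere.radius == pytest.approx(2.0, abs=1e-9)

    def test_mean_diameter(self):
        edges = CellEdgeSet(
            "c1", edge_points=AXIS_POINTS[:4], diameters=[4.0, 4.2, 3.8, 4.0]
        )
        sphere = fit_sphere(edges, method="mean_diameter")
        assert sphere.radius == pytest.approx(2.0)
        np.testing.assert_allclose(sphere.center, AXIS_POINTS[:4].mean(axis=0))

    def test_coplanar_points_error_names_fallback(self):
        pts = np.array([[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0], [1, 1, 0]], float)
        with pytest.raises(ValidationError, match="mean_diameter"):
            fit_sphere(CellEdgeSet("c1", edge_points=pts), method="least_squares_edges")

    def test_noisy_recovery_within_three_percent(self):
        edges = simulate_cell(2.0, edge_noise=0.05, n_edges=12, seed=9)
        sphere = fit_sphere(edges)
        assert sphere.radius == pytest.approx(2.0, rel=0.03)

    def test_noisy_fit_matches_brute_force_oracle(self):
        """Least-squares fit agrees with a grid search over centre and
        radius minimizing the squared geometric residual."""
        edges = simulate_cell(2.0, edge_noise=0.05, n_edges=10, seed=4)
        sphere = fit_sphere(edges)
        pts = edges.edge_points
        best = (None, np.inf)
        for cx in np.linspace(-0.2, 0.2, 21):
            for cy in np.linspace(-0.2, 0.2, 21):
                for cz in np.linspace(-0.2, 0.2, 21):
                    c = np.array([cx, cy, cz])
                    d = np.linalg.norm(pts - c, axis=1)
                    r = d.mean()  # optimal radius for fixed centre
                    loss = np.sum((d - r) ** 2)
                    if loss < best[1]:
                        best = ((c, r), loss)
        (c_star, r_star), _ = best
        assert sphere.radius == pytest.approx(r_star, abs=0.03)
        np.testing.assert_allclose(sphere.center, c_star, atol=0.03)


class TestPeripheryDistance:
    @pytest.fixture
    def sphere(self):
        return fit_sphere(CellEdgeSet("c1", edge_points=AXIS_POINTS))

    def test_center_is_half(self, sphere):
        pos = relative_periphery_distance(sphere.center, sphere)
        assert pos.relative_distance == pytest.approx(0.5)

    def test_membrane_is_zero(self, sphere):
        pos = relative_periphery_distance([2.0, 0.0, 0.0], sphere)
        assert pos.relative_distance == pytest.approx(0.0)

    def test_half_radius_is_quarter(self, sphere):
        pos = relative_periphery_distance([1.0, 0.0, 0.0], sphere)
        assert pos.relative_distance == pytest.approx(0.25)

    def test_outside_sphere_clips_to_zero_with_warning(self, sphere):
        with pytest.warns(UserWarning, match="outside"):
            pos = relative_periphery_distance([3.0, 0.0, 0.0], sphere)
        assert pos.relative_distance == 0.0

    def test_monotone_decreasing_in_radius(self, sphere):
        radii = np.linspace(0, 2.0, 15)
        rel = [
            relative_periphery_distance([r, 0.0, 0.0], sphere).relative_distance
            for r in radii
        ]
        assert np.all(np.diff(rel) < 0)

    def test_zero_radius_sphere_rejected(self):
        with pytest.raises(ValidationError):
            FittedSphere("c", np.zeros(3), 0.0, "mean_diameter")

    def test_peripheral_bias_lowers_median_relative_distance(self):
        """Synthetic aggregates drawn with peripheral bias sit closer to
        the membrane than uniformly drawn ones."""
        sphere = FittedSphere("c", np.zeros(3), 2.0, "mean_diameter")
        uniform = simulate_aggregate_positions(sphere, 2000, peripheral_bias=0.0, seed=1)
        biased = simulate_aggregate_positions(sphere, 2000, peripheral_bias=6.0, seed=2)

        def med(positions):
            return np.median(
                [
                    relative_periphery_distance(p, sphere).relative_distance
                    for p in positions
                ]
            )

        assert med(biased) < med(uniform)
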