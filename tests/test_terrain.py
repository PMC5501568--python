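"""Terrain derivatives, IDW interpolation and feature-matrix assembly."""

import numpy as np
import pytest

from terrazone.terrain import (
    GridField,
    GridGeometryError,
    PointSamples,
    build_feature_matrix,
    denormalize_features,
    derive_aspect,
    derive_plan_curvature,
    derive_slope,
    idw_interpolate,
    normalize_features,
)

from .conftest import smooth_random_dem


def plane_dem(a_x=0.0, a_y=0.0, c=100.0, rows=8, cols=10, cell=10.0):
    y, x = np.meshgrid(cell * np.arange(rows), cell * np.arange(cols), indexing="ij")
    return GridField(c + a_x * x + a_y * y, cell_size=cell, attribute_name="elevation")


def _oracle_gradients(z, cell):
    """Independent double-loop central/one-sided finite differences."""
    rows, cols = z.shape
    fx = np.zeros_like(z)
    fy = np.zeros_like(z)
    for r in range(rows):
        for c in range(cols):
            if 0 < c < cols - 1:
                fx[r, c] = (z[r, c + 1] - z[r, c - 1]) / (2 * cell)
            elif c == 0:
                fx[r, c] = (z[r, 1] - z[r, 0]) / cell
            else:
                fx[r, c] = (z[r, -1] - z[r, -2]) / cell
            if 0 < r < rows - 1:
                fy[r, c] = (z[r + 1, c] - z[r - 1, c]) / (2 * cell)
            elif r == 0:
                fy[r, c] = (z[1, c] - z[0, c]) / cell
            else:
                fy[r, c] = (z[-1, c] - z[-2, c]) / cell
    return fx, fy


class TestSlope:
    def test_flat_surface_has_zero_slope(self):
        s = derive_slope(plane_dem())
        assert np.allclose(s.values, 0.0)

    def test_one_percent_plane(self):
        # z = 0.01 x -> slope exactly 1% everywhere, edges included
        s = derive_slope(plane_dem(a_x=0.01))
        assert np.allclose(s.values, 1.0, atol=1e-12)

    def test_matches_finite_difference_oracle(self, random_dem):
        s = derive_slope(random_dem).values
        fx, fy = _oracle_gradients(random_dem.values, random_dem.cell_size)
        expected = 100.0 * np.hypot(fx, fy)
        assert np.allclose(s, expected, rtol=1e-9)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            derive_slope(GridField(np.zeros((2, 2))))

    def test_nodata_poisons_neighborhood(self):
        dem = plane_dem(a_x=0.01)
        dem.values[3, 4] = np.nan
        dem.nodata_mask[3, 4] = True
        s = derive_slope(dem)
        assert s.nodata_mask[2:5, 3:6].all()
        assert not s.nodata_mask[0, 0]


class TestAspect:
    @pytest.mark.parametrize(
        "ax, ay, expected",
        [
            (0.0, 0.02, 180.0),   # rises north -> drains south
            (-0.02, 0.0, 90.0),   # falls east -> drains east
            (0.0, -0.02, 0.0),    # falls north -> drains north
            (0.02, 0.02, 225.0),  # rises NE -> drains SW
        ],
    )
    def test_plane_aspect(self, ax, ay, expected):
        a = derive_aspect(plane_dem(a_x=ax, a_y=ay))
        assert np.allclose(a.values, expected)

    def test_flat_cells_have_no_aspect(self):
        a = derive_aspect(plane_dem())
        assert a.nodata_mask.all()

    def test_matches_atan2_oracle(self, random_dem):
        a = derive_aspect(random_dem).values
        fx, fy = _oracle_gradients(random_dem.values, random_dem.cell_size)
        expected = np.degrees(np.arctan2(-fx, -fy)) % 360.0
        ok = np.isfinite(a)
        delta = np.abs(a[ok] - expected[ok]) % 360.0
        assert np.all(np.minimum(delta, 360.0 - delta) < 1e-9)

    def test_range(self, random_dem):
        a = derive_aspect(random_dem)
        vals = a.values[~a.nodata_mask]
        assert np.all((vals >= 0) & (vals < 360))


class TestPlanCurvature:
    def test_plane_is_zero(self):
        c = derive_plan_curvature(plane_dem(a_x=0.01, a_y=0.004))
        assert np.allclose(c.values, 0.0, atol=1e-12)

    @pytest.mark.parametrize("a", [1e-4, -1e-4])
    def test_circular_paraboloid_constant(self, a):
        # z = a (x^2 + y^2): the quadratic-coefficient plan curvature is the
        # constant 2a (positive = convergent bowl) away from the flat apex
        cell = 10.0
        y, x = np.meshgrid(cell * (np.arange(9) - 4), cell * (np.arange(9) - 4),
                           indexing="ij")
        dem = GridField(a * (x ** 2 + y ** 2), cell_size=cell)
        curv = derive_plan_curvature(dem).values
        interior = np.ones_like(curv, dtype=bool)
        interior[4, 4] = False  # apex has zero gradient -> curvature 0 by rule
        assert np.allclose(curv[interior], 2 * a, rtol=1e-9)
        assert curv[4, 4] == 0.0

    def test_flat_grid_zero(self):
        assert np.allclose(derive_plan_curvature(plane_dem()).values, 0.0)


class TestInvariance:
    def test_translation_leaves_derivatives_unchanged(self, random_dem):
        shifted = GridField(random_dem.values + 123.4, cell_size=random_dem.cell_size)
        assert np.allclose(derive_slope(random_dem).values,
                           derive_slope(shifted).values)
        a0, a1 = derive_aspect(random_dem), derive_aspect(shifted)
        assert np.allclose(a0.values[~a0.nodata_mask], a1.values[~a1.nodata_mask])
        assert np.allclose(derive_plan_curvature(random_dem).values,
                           derive_plan_curvature(shifted).values)

    def test_vertical_scaling(self, random_dem):
        c = 2.5
        scaled = GridField(c * random_dem.values, cell_size=random_dem.cell_size)
        assert np.allclose(derive_slope(scaled).values,
                           c * derive_slope(random_dem).values)
        a0, a1 = derive_aspect(random_dem), derive_aspect(scaled)
        assert np.allclose(a0.values[~a0.nodata_mask], a1.values[~a1.nodata_mask])


class TestIDW:
    def template(self, rows=6, cols=7):
        return GridField(np.zeros((rows, cols)), cell_size=10.0)

    def test_exact_hit_returns_observation(self, rng):
        pts = PointSamples([20.0, 51.0], [30.0, 7.0], [5.0, 9.0])
        out = idw_interpolate(pts, self.template())
        assert out.values[3, 2] == 5.0  # cell center (20, 30)

    def test_equidistant_pair_averages(self):
        pts = PointSamples([0.0, 40.0], [0.0, 0.0], [10.0, 20.0])
        for power in (0.5, 1.0, 2.0, 4.0):
            out = idw_interpolate(pts, self.template(), power=power)
            assert out.values[0, 2] == pytest.approx(15.0)  # center (20, 0)

    def test_matches_double_loop_oracle(self, rng):
        n = 20
        pts = PointSamples(rng.uniform(-5, 70, n), rng.uniform(-5, 60, n),
                           rng.normal(50, 10, n))
        tpl = self.template()
        power, k = 1.7, 8
        out = idw_interpolate(pts, tpl, power=power, max_neighbors=k)
        for r in range(tpl.shape[0]):
            for c in range(tpl.shape[1]):
                gx, gy = c * 10.0, r * 10.0
                d = np.hypot(pts.x - gx, pts.y - gy)
                near = np.argsort(d)[:k]
                w = d[near] ** (-power)
                expected = np.sum(w * pts.values[near]) / np.sum(w)
                assert out.values[r, c] == pytest.approx(expected, rel=1e-9)

    def test_bounded_by_observations(self, rng):
        n = 15
        pts = PointSamples(rng.uniform(0, 60, n), rng.uniform(0, 50, n),
                           rng.normal(0, 1, n))
        out = idw_interpolate(pts, self.template(), power=2.0, max_neighbors=5)
        assert out.values.min() >= pts.values.min() - 1e-12
        assert out.values.max() <= pts.values.max() + 1e-12

    def test_empty_points_rejected(self):
        with pytest.raises(ValueError):
            idw_interpolate(PointSamples([], [], []), self.template())


class TestFeatureMatrix:
    def layers(self, n=3, rows=2, cols=2):
        return [
            GridField(np.arange(rows * cols, dtype=float).reshape(rows, cols) + i,
                      cell_size=10.0, attribute_name=f"a{i}")
            for i in range(n)
        ]

    def test_counts(self):
        fm = build_feature_matrix(self.layers())
        assert fm.data.shape == (4, 3)

    def test_nodata_intersection_drops_row(self):
        layers = self.layers()
        layers[1].values[0, 1] = np.nan
        layers[1].nodata_mask[0, 1] = True
        fm = build_feature_matrix(layers)
        assert fm.data.shape == (3, 3)
        assert not any((r, c) == (0, 1) for r, c in fm.location_index)

    def test_study_scale_matrix(self, rng):
        # 75 x 94 = 7050 valid cells with six layers reproduces the
        # 7050 x 6 input-matrix geometry of a full field survey
        dem = smooth_random_dem(rng, rows=75, cols=94)
        layers = [dem, derive_slope(dem), derive_plan_curvature(dem)]
        layers += [GridField(rng.normal(size=dem.shape), cell_size=10.0,
                             attribute_name=n) for n in ("e1", "e2", "e3")]
        fm = build_feature_matrix(layers)
        assert fm.data.shape == (7050, 6)

    def test_geometry_mismatch_rejected(self):
        layers = self.layers()
        layers[1] = GridField(layers[1].values, cell_size=5.0)
        with pytest.raises(GridGeometryError):
            build_feature_matrix(layers)


class TestNormalization:
    def test_zero_mean_unit_sd(self, rng):
        fm = build_feature_matrix([
            GridField(rng.normal(5, 3, (6, 6)), attribute_name="a"),
            GridField(rng.uniform(0, 100, (6, 6)), attribute_name="b"),
        ])
        z = normalize_features(fm)
        assert np.allclose(z.data.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(z.data.std(axis=0), 1.0, atol=1e-9)

    def test_standardized_input_unchanged(self, rng):
        raw = rng.normal(size=(50, 2))
        raw = (raw - raw.mean(0)) / raw.std(0)
        fm = build_feature_matrix([
            GridField(raw[:, i].reshape(5, 10), attribute_name=f"f{i}")
            for i in range(2)
        ])
        z = normalize_features(fm)
        assert np.allclose(z.data, fm.data, atol=1e-9)

    def test_round_trip(self, rng):
        fm = build_feature_matrix([
            GridField(rng.normal(5, 3, (6, 6)), attribute_name="a"),
        ])
        back = denormalize_features(normalize_features(fm))
        assert np.allclose(back.data, fm.data, atol=1e-9)

    def test_constant_column_named_in_error(self):
        fm = build_feature_matrix([
            GridField(np.ones((4, 4)), attribute_name="flatcol"),
            GridField(np.arange(16, dtype=float).reshape(4, 4), attribute_name="ok"),
        ])
        with pytest.raises(ValueError, match="flatcol"):
            normalize_features(fm)
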