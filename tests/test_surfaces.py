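import numpy as np
import pytest

from nestscape.grids import Raster
from nestscape.surfaces import (
    TRANSFORM_FAMILIES,
    TransformSpec,
    WINDOW_SIDES,
    candidate_surfaces,
    patch_metrics,
    place_subregion,
    pland_moving_window,
    transform_curve,
    transform_surface,
    window_area_km2,
)


class TestPlandMovingWindow:
    def test_homogeneous_raster_is_100_percent(self):
        r = Raster(np.full((20, 20), 3), cell_size=30.0)
        surface = pland_moving_window(r, 3, 250.0)
        np.testing.assert_allclose(surface.values, 100.0)

    def test_checkerboard_approaches_50_percent(self):
        rows, cols = np.indices((60, 60))
        r = Raster(((rows + cols) % 2).astype(np.uint8), cell_size=10.0)
        surface = pland_moving_window(r, 1, 250.0)  # 25-cell window >> cell
        interior = surface.values[15:-15, 15:-15]
        assert np.all(np.abs(interior - 50.0) <= 1.0)

    def test_window_area_for_250m_window(self):
        assert window_area_km2(250.0) == pytest.approx(0.0625)

    def test_absent_class_warns_and_returns_zero(self):
        r = Raster(np.zeros((10, 10), dtype=np.uint8), cell_size=30.0)
        with pytest.warns(UserWarning, match="absent"):
            surface = pland_moving_window(r, 7, 250.0)
        np.testing.assert_allclose(surface.values, 0.0)

    def test_edge_truncation_keeps_percentages_valid(self):
        rng = np.random.default_rng(0)
        r = Raster(rng.integers(0, 3, size=(30, 30)).astype(np.uint8), cell_size=30.0)
        surface = pland_moving_window(r, 0, 500.0)
        assert np.nanmin(surface.values) >= 0 and np.nanmax(surface.values) <= 100

    def test_translation_equivariance_away_from_edges(self):
        rng = np.random.default_rng(1)
        vals = rng.integers(0, 2, size=(40, 40)).astype(np.uint8)
        shifted = np.roll(vals, 3, axis=1)
        a = pland_moving_window(Raster(vals, 30.0), 1, 250.0).values
        b = pland_moving_window(Raster(shifted, 30.0), 1, 250.0).values
        np.testing.assert_allclose(a[10:-10, 10:-23], b[10:-10, 13:-20])

    def test_window_smaller_than_cell_rejected(self):
        r = Raster(np.zeros((5, 5)), cell_size=100.0)
        with pytest.raises(ValueError, match="cell size"):
            pland_moving_window(r, 0, 50.0)


class TestTransforms:
    @pytest.mark.parametrize("family", [f for f in TRANSFORM_FAMILIES if not f.startswith("inverse")])
    def test_non_inverse_families_start_at_resistance_1(self, family):
        spec = TransformSpec(family)
        x = 1.0 if family.startswith("reverse") else 0.0
        assert transform_curve(np.array([x]), spec)[0] == pytest.approx(0.0)

    def test_linear_full_cover_is_max_resistance(self):
        p = Raster(np.array([[100.0]]), cell_size=1.0)
        surf = transform_surface(p, TransformSpec("linear"))
        assert surf.raster.values[0, 0] == pytest.approx(100.0)

    @pytest.mark.parametrize(
        "plain_family,inverse_family",
        [
            ("monomolecular", "inverse monomolecular"),
            ("reverse monomolecular", "inverse-reverse monomolecular"),
            ("ricker", "inverse ricker"),
            ("reverse ricker", "inverse-reverse ricker"),
        ],
    )
    def test_inverse_is_101_minus_value(self, plain_family, inverse_family):
        # 1 + (M-1)(1-g) = (M+1) - (1 + (M-1) g) for M = 100
        p = Raster(np.linspace(0, 100, 21).reshape(3, 7), cell_size=1.0)
        plain = transform_surface(p, TransformSpec(plain_family))
        inverse = transform_surface(p, TransformSpec(inverse_family))
        np.testing.assert_allclose(
            inverse.raster.values, 101.0 - plain.raster.values, atol=1e-10
        )

    def test_families_map_unit_interval_into_unit_interval(self):
        x = np.linspace(0, 1, 201)
        for family in TRANSFORM_FAMILIES:
            g = transform_curve(x, TransformSpec(family))
            assert np.all((g >= -1e-12) & (g <= 1 + 1e-12)), family

    def test_monomolecular_monotone_ricker_unimodal(self):
        x = np.linspace(0, 1, 201)
        mono = transform_curve(x, TransformSpec("monomolecular"))
        assert np.all(np.diff(mono) > 0)
        ricker = transform_curve(x, TransformSpec("ricker", shape=2.0))
        peak = np.argmax(ricker)
        assert np.all(np.diff(ricker[: peak + 1]) >= 0)
        assert np.all(np.diff(ricker[peak:]) <= 0)
        assert ricker.max() == pytest.approx(1.0)

    def test_out_of_range_input_rejected(self):
        p = Raster(np.array([[150.0]]), cell_size=1.0)
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            transform_surface(p, TransformSpec("linear"))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            TransformSpec("quadratic")


class TestCandidateSurfaces:
    def test_exactly_45_uniquely_labeled_candidates(self, small_landscape):
        surfaces = candidate_surfaces(small_landscape, 2)
        assert len(surfaces) == len(WINDOW_SIDES) * len(TRANSFORM_FAMILIES) == 45
        labels = [s.label for s in surfaces]
        assert len(set(labels)) == 45

    def test_values_within_resistance_bounds(self, small_landscape):
        for s in candidate_surfaces(small_landscape, 1):
            vals = s.raster.values[np.isfinite(s.raster.values)]
            assert vals.min() >= 1.0 - 1e-9 and vals.max() <= 100.0 + 1e-9


class TestPatchMetrics:
    def test_single_cell_patch_has_zero_correlation_length(self):
        vals = np.zeros((10, 10), dtype=np.uint8)
        vals[4, 4] = 1
        m = patch_metrics(Raster(vals, 10.0), 1)
        assert m.n_patches == 1 and m.correlation_length == 0.0

    def test_one_patch_in_100ha_is_density_one(self):
        # 100 x 100 cells at 10 m = 1 km^2 = 100 ha
        vals = np.zeros((100, 100), dtype=np.uint8)
        vals[10:20, 10:20] = 1
        m = patch_metrics(Raster(vals, 10.0), 1)
        assert m.patch_density == pytest.approx(1.0)

    def test_diagonal_cells_queen_vs_rook(self):
        vals = np.zeros((5, 5), dtype=np.uint8)
        vals[1, 1] = vals[2, 2] = 1
        assert patch_metrics(Raster(vals, 10.0), 1, connectivity="queen").n_patches == 1
        assert patch_metrics(Raster(vals, 10.0), 1, connectivity="rook").n_patches == 2

    def test_absent_class_gives_zero_metrics(self):
        m = patch_metrics(Raster(np.zeros((5, 5), dtype=np.uint8), 10.0), 9)
        assert m == type(m)(0.0, 0.0, 0.0, 0)

    def test_cohesion_bounded_and_higher_for_consolidated_patches(self):
        blob = np.zeros((40, 40), dtype=np.uint8)
        blob[10:30, 10:30] = 1
        scattered = np.zeros((40, 40), dtype=np.uint8)
        scattered[::4, ::4] = 1
        c_blob = patch_metrics(Raster(blob, 10.0), 1).cohesion
        c_scat = patch_metrics(Raster(scattered, 10.0), 1).cohesion
        assert 0 <= c_scat < c_blob <= 100

    def test_correlation_length_scales_with_patch_size(self):
        small = np.zeros((40, 40), dtype=np.uint8)
        small[18:22, 18:22] = 1
        big = np.zeros((40, 40), dtype=np.uint8)
        big[10:30, 10:30] = 1
        cl_small = patch_metrics(Raster(small, 10.0), 1).correlation_length
        cl_big = patch_metrics(Raster(big, 10.0), 1).correlation_length
        assert cl_big > cl_small > 0

    def test_invalid_connectivity_rejected(self):
        with pytest.raises(ValueError, match="rook"):
            patch_metrics(Raster(np.zeros((3, 3)), 1.0), 0, connectivity="bishop")


class TestPlaceSubregion:
    def test_homogeneous_raster_objective_zero(self):
        r = Raster(np.full((20, 20), 2, dtype=np.uint8), cell_size=100.0)
        out = place_subregion(r, 500.0)
        assert out["objective"] == 0.0
        assert out["within_tolerance"]

    def test_fine_stride_never_worse_than_coarse(self, small_landscape):
        fine = place_subregion(small_landscape, 900.0, stride=1)
        coarse = place_subregion(small_landscape, 900.0, stride=4)
        assert fine["objective"] <= coarse["objective"] + 1e-12

    def test_bounds_align_with_offset(self, small_landscape):
        out = place_subregion(small_landscape, 600.0, stride=2)
        xmin, ymin, xmax, ymax = out["bounds"]
        assert xmax - xmin == pytest.approx(600.0)
        assert ymax - ymin == pytest.approx(600.0)

    def test_oversized_subregion_rejected(self, small_landscape):
        with pytest.raises(ValueError, match="fit inside"):
            place_subregion(small_landscape, 10_000.0)

    def test_default_tolerance_is_6_3_percent(self):
        import inspect

        sig = inspect.signature(place_subregion)
        assert sig.parameters["tolerance"].default == 6.3
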