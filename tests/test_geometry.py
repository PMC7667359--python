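"""Caliper geometry: Feret diameters, orthogonal widths, slice handling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strokevol.geometry import (
    EmptyMaskError,
    LesionImage,
    SliceMask,
    count_lesion_slices,
    load_mask,
    max_feret_diameter,
    orthogonal_diameter,
    select_measurement_slice,
    slice_masks,
    volumetric_volume,
)
from strokevol.synthetic import SyntheticLesionSpec, rasterize_lesion, write_cohort

from conftest import (
    brute_force_feret,
    brute_force_projection_width,
    digital_ellipse,
    random_mask,
    single_slice_image,
)


def rect_slice(n_rows, n_cols, spacing=(1.0, 1.0)):
    return SliceMask(np.ones((n_rows, n_cols), bool), spacing, 0)


class TestMaxFeret:
    def test_single_pixel_measures_its_diagonal(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        a, direction, endpoints = max_feret_diameter(SliceMask(mask, (1.0, 1.0), 0))
        assert a == pytest.approx(0.1 * np.sqrt(2))
        assert np.linalg.norm(direction) == pytest.approx(1.0)

    def test_filled_rectangle_measures_corner_diagonal(self):
        a, _, endpoints = max_feret_diameter(rect_slice(50, 20))
        assert a == pytest.approx(np.sqrt(50**2 + 20**2) / 10)
        # endpoints are opposite rectangle corners
        assert np.linalg.norm(endpoints[0] - endpoints[1]) == pytest.approx(10 * a)

    def test_rotated_digital_ellipse_recovers_major_axis(self):
        slc = digital_ellipse(46.0, 24.0, angle_deg=30.0)
        a, _, _ = max_feret_diameter(slc)
        assert a == pytest.approx(9.2, abs=0.15)
        assert a == pytest.approx(brute_force_feret(slc), abs=1e-12)

    def test_empty_slice_raises(self):
        with pytest.raises(EmptyMaskError):
            max_feret_diameter(SliceMask(np.zeros((4, 4), bool), (1.0, 1.0), 0))

    def test_anisotropic_spacing_scales_physical_length(self):
        row = np.zeros((3, 10), bool)
        row[1, :] = True
        narrow, _, _ = max_feret_diameter(SliceMask(row, (1.0, 1.0), 0))
        wide, _, _ = max_feret_diameter(SliceMask(row, (1.0, 2.0), 0))
        # 10 px row: 10 mm + pixel height vs 20 mm + pixel height
        assert narrow == pytest.approx(np.sqrt(10**2 + 1) / 10)
        assert wide == pytest.approx(np.sqrt(20**2 + 1) / 10)

    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(st.integers(0, 10_000))
    def test_hull_feret_equals_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        slc = SliceMask(random_mask(rng), (1.0, 1.0), 0)
        a, _, _ = max_feret_diameter(slc)
        assert a == pytest.approx(brute_force_feret(slc), abs=1e-12)

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_adding_pixels_never_shrinks_feret(self, seed):
        rng = np.random.default_rng(seed)
        mask = random_mask(rng)
        a_before, _, _ = max_feret_diameter(SliceMask(mask, (1.0, 1.0), 0))
        grown = mask.copy()
        grown[rng.integers(mask.shape[0]), rng.integers(mask.shape[1])] = True
        a_after, _, _ = max_feret_diameter(SliceMask(grown, (1.0, 1.0), 0))
        assert a_after >= a_before - 1e-12

    @pytest.mark.parametrize("angle", np.linspace(0, 180, 9, endpoint=False))
    def test_rotation_invariance_within_two_pixel_diagonals(self, angle):
        slc = digital_ellipse(46.0, 24.0, angle_deg=angle)
        a, _, _ = max_feret_diameter(slc)
        assert abs(a - 9.2) <= 2 * np.sqrt(2) / 10


class TestOrthogonalDiameter:
    def test_rectangle_width_perpendicular_to_long_axis(self):
        b = orthogonal_diameter(rect_slice(50, 20), np.array([1.0, 0.0]))
        assert b == pytest.approx(2.0)

    def test_single_pixel_wide_line(self):
        line = np.zeros((1, 30), bool)
        line[0, :] = True
        b = orthogonal_diameter(SliceMask(line, (1.0, 1.0), 0), np.array([0.0, 1.0]))
        assert b == pytest.approx(0.1)

    def test_rotated_ellipse_minor_axis(self):
        slc = digital_ellipse(46.0, 24.0, angle_deg=30.0)
        _, direction, _ = max_feret_diameter(slc)
        b = orthogonal_diameter(slc, direction)
        assert b == pytest.approx(4.8, abs=0.15)

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError):
            orthogonal_diameter(rect_slice(5, 5), np.zeros(2))

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(st.integers(0, 10_000), st.floats(0, np.pi, allow_nan=False))
    def test_feret_dominates_any_projection_width(self, seed, theta):
        rng = np.random.default_rng(seed)
        slc = SliceMask(random_mask(rng), (1.0, 1.0), 0)
        a, _, _ = max_feret_diameter(slc)
        direction = np.array([np.cos(theta), np.sin(theta)])
        b = orthogonal_diameter(slc, direction)
        assert b <= a + 1e-12
        assert b == pytest.approx(
            brute_force_projection_width(slc, direction), abs=1e-12
        )


class TestSliceSelection:
    def test_equatorial_slice_of_ellipsoid_wins(self):
        spec = SyntheticLesionSpec(semi_axes=(30.0, 46.0, 24.0), spacing=(5.0, 1.0, 1.0))
        image = rasterize_lesion(spec)
        meas = select_measurement_slice(image)
        equator = (image.mask.shape[0] - 1) // 2
        assert meas.slice_index == equator
        assert meas.a_cm == pytest.approx(9.2, abs=0.15)
        assert meas.b_cm == pytest.approx(4.8, abs=0.15)
        assert meas.a_cm >= meas.b_cm

    def test_single_voxel_image(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        meas = select_measurement_slice(LesionImage(mask, (5.0, 1.0, 1.0)))
        assert meas.slice_index == 1
        assert meas.a_cm == pytest.approx(0.1 * np.sqrt(2))
        assert meas.b_cm == pytest.approx(meas.a_cm)

    def test_tie_breaks_to_lowest_slice(self):
        mask = np.zeros((4, 5, 5), bool)
        mask[1, 1:4, 1:4] = True
        mask[3, 1:4, 1:4] = True
        meas = select_measurement_slice(LesionImage(mask, (5.0, 1.0, 1.0)))
        assert meas.slice_index == 1

    def test_b_direction_is_exactly_perpendicular(self):
        slc = digital_ellipse(30.0, 12.0, angle_deg=17.0)
        image = single_slice_image(slc.mask)
        meas = select_measurement_slice(image)
        b_dir = meas.b_endpoints[1] - meas.b_endpoints[0]
        b_dir = b_dir / np.linalg.norm(b_dir)
        assert abs(float(b_dir @ meas.a_direction)) < 1e-9

    def test_empty_image_raises(self):
        with pytest.raises(EmptyMaskError):
            select_measurement_slice(LesionImage(np.zeros((2, 2, 2)), (5.0, 1.0, 1.0)))


class TestSliceUtilities:
    def test_slice_masks_split_and_flag(self):
        mask = np.zeros((10, 4, 4), bool)
        mask[3, 2, 1] = True
        slices = slice_masks(LesionImage(mask, (5.0, 1.0, 1.0)))
        assert [s.slice_index for s in slices] == list(range(10))
        assert slices[3].mask[2, 1] and not slices[3].empty
        assert all(slices[i].empty for i in range(10) if i != 3)

    def test_count_skips_gaps(self):
        mask = np.zeros((7, 3, 3), bool)
        mask[2, 1, 1] = True
        mask[5, 1, 1] = True
        image = LesionImage(mask, (5.0, 1.0, 1.0))
        assert count_lesion_slices(image) == 2
        assert count_lesion_slices(LesionImage(np.zeros((7, 3, 3)), (5.0, 1.0, 1.0))) == 0

    def test_thirteen_slice_phantom_counts_thirteen(self):
        spec = SyntheticLesionSpec(semi_axes=(31.0, 46.0, 24.0), spacing=(5.0, 1.0, 1.0))
        assert count_lesion_slices(rasterize_lesion(spec)) == 13


class TestVolumetry:
    def test_voxel_count_times_voxel_volume(self):
        mask = np.zeros((10, 10, 10), bool)
        mask.flat[:1000] = True
        assert volumetric_volume(LesionImage(mask, (1.0, 1.0, 1.0))) == pytest.approx(1.0)

    def test_digital_sphere_close_to_analytic(self):
        spec = SyntheticLesionSpec(semi_axes=(20.0, 20.0, 20.0), spacing=(1.0, 1.0, 1.0))
        vol = volumetric_volume(rasterize_lesion(spec))
        analytic = 4 / 3 * np.pi * 20**3 / 1000
        assert vol == pytest.approx(analytic, rel=0.02)

    def test_empty_mask_is_zero(self):
        assert volumetric_volume(LesionImage(np.zeros((3, 3, 3)), (5.0, 1.0, 1.0))) == 0.0


class TestNiftiRoundTrip:
    def test_load_mask_recovers_spacing_and_slice_axis(self, tmp_path):
        spec = SyntheticLesionSpec(
            semi_axes=(12.0, 20.0, 9.0), spacing=(4.0, 1.0, 1.0), patient_id="P0000"
        )
        write_cohort([spec], tmp_path)
        image = load_mask(tmp_path / "P0000.nii.gz")
        assert image.spacing == (4.0, 1.0, 1.0)
        assert image.patient_id == "P0000"
        np.testing.assert_array_equal(image.mask, rasterize_lesion(spec).mask)
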