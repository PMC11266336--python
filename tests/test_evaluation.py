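"""Recovery coefficients, calibration factor, FWHM estimation, regression."""

import numpy as np
import pytest

from spectpvc import reference
from spectpvc.core import ActivityImage, EmptyMaskError, VoxelGrid
from spectpvc.evaluation import (
    apply_background_heterogeneity,
    background_rc,
    bias_vs_sv_regression,
    calibration_factor,
    cf_decrease_percent,
    estimate_fwhm,
    peripheral_shell_rc,
    recovery_coefficient,
)
from spectpvc.phantom import BACKGROUND_LABEL, LUNG_LABEL, assemble_phantom
from spectpvc.psf import PSFModel, convolve_values
from spectpvc.shapes import Capillary, EllipticalCylinder, rasterize_shape


class TestRecoveryCoefficient:
    def test_uniform_image_gives_rc_one(self):
        grid = VoxelGrid((8, 8, 8), (2.21,) * 3)
        image = ActivityImage(grid, np.full((8, 8, 8), 55.0))
        rec = recovery_coefficient(image, np.ones((8, 8, 8), bool), 55.0)
        assert rec.rc == 1.0 and rec.c == 55.0

    def test_empty_mask_and_bad_ccal_rejected(self):
        grid = VoxelGrid((4, 4, 4), (1.0,) * 3)
        image = ActivityImage(grid, np.ones((4, 4, 4)))
        with pytest.raises(EmptyMaskError):
            recovery_coefficient(image, np.zeros((4, 4, 4), bool), 1.0)
        with pytest.raises(ValueError):
            recovery_coefficient(image, np.ones((4, 4, 4), bool), 0.0)

    def test_truth_interior_kidney_rc_is_one(self, iec1_run):
        # fractional truth: fully interior voxels carry the pure target
        # concentration, so the eroded-mask RC is exactly 1
        from spectpvc.core import erode_mask

        truth, labels = assemble_phantom(iec1_run.spec, boundary="fractional", validate=False)
        interior = erode_mask(labels.mask(1), 2.5, labels.grid.spacing)
        rec = recovery_coefficient(truth, interior, iec1_run.spec.target_conc)
        assert rec.rc == pytest.approx(1.0, abs=1e-6)

    def test_truth_full_mask_rc_is_one_in_labels_mode(self, iec1_run):
        for label in (1, 2, 8):
            rec = recovery_coefficient(
                iec1_run.truth, iec1_run.labels.mask(label), iec1_run.spec.target_conc
            )
            assert rec.rc == pytest.approx(1.0, abs=1e-12)

    def test_observed_kidney_rc_matches_forward_model_prediction(self, iec1_run):
        # the uncorrected RC is exactly what the blur model predicts
        predicted = convolve_values(
            iec1_run.truth.values, iec1_run.psf, iec1_run.truth.grid.spacing
        )
        mask = iec1_run.labels.mask(1)
        rec = recovery_coefficient(iec1_run.observed, mask, iec1_run.spec.target_conc)
        assert rec.rc == pytest.approx(predicted[mask].mean() / iec1_run.spec.target_conc)
        assert 0.4 < rec.rc < 0.9  # strong, plausible PVE for the small kidney

    def test_background_rc_on_truth_and_observed(self, iec1_run):
        truth_rec = background_rc(iec1_run.truth, iec1_run.labels, iec1_run.spec.background_conc)
        assert truth_rec.rc == pytest.approx(1.0, abs=1e-12)
        obs_rec = background_rc(iec1_run.observed, iec1_run.labels, iec1_run.spec.background_conc)
        assert obs_rec.rc == pytest.approx(1.0, abs=0.01)  # 3 cm erosion clears spill-over

    def test_shell_of_truth_sits_at_background_level(self, iec1_run):
        rec = peripheral_shell_rc(
            iec1_run.truth, iec1_run.labels.mask(1), iec1_run.labels, iec1_run.spec.background_conc
        )
        assert rec.rc == pytest.approx(1.0, abs=1e-12)


class TestCalibration:
    def test_cf_arithmetic(self):
        grid = VoxelGrid((96, 96, 80), (2.21,) * 3, (-105.0, -105.0, -87.0))
        image = ActivityImage(grid, np.full(grid.shape, 100.0), unit="counts")
        result = calibration_factor(image, c_cal=50.0)
        assert result.cf == pytest.approx(2.0)
        assert result.n_ave == pytest.approx(100.0)

    def test_uniform_cylinder_recovers_reference_cf(self):
        # count-rate image painted at CF x C_cal inside the phantom
        grid = VoxelGrid((100, 100, 84), (2.21,) * 3)
        origin = -(np.array(grid.shape) - 1) / 2 * 2.21
        grid = VoxelGrid(grid.shape, grid.spacing, tuple(origin))
        phantom = EllipticalCylinder((0, 0, 0), (105.0, 105.0), 91.5)
        occ = rasterize_shape(phantom, grid, supersample=2)
        c_cal = 848.3
        values = occ * reference.CALIBRATION_FACTOR * c_cal
        image = ActivityImage(grid, values, unit="counts")
        result = calibration_factor(image, c_cal=c_cal)
        assert result.cf == pytest.approx(reference.CALIBRATION_FACTOR, rel=1e-6)

    def test_voi_outside_grid_rejected(self):
        grid = VoxelGrid((20, 20, 20), (2.21,) * 3)
        image = ActivityImage(grid, np.ones(grid.shape))
        with pytest.raises(ValueError, match="outside"):
            calibration_factor(image, c_cal=1.0)

    def test_printed_cf_extremes_give_2p45_percent_decrease(self):
        low, high = reference.CALIBRATION_FACTOR_EXTREMES
        assert cf_decrease_percent(low, high) == pytest.approx(2.45, abs=0.01)


class TestEstimateFwhm:
    def line_image(self, line_axis, blur, n=73, spacing=2.21):
        origin = -(n - 1) / 2.0 * spacing
        grid = VoxelGrid((n, n, n), (spacing,) * 3, (origin,) * 3)
        capillary = Capillary((0, 0, 0), radius=0.75, half_length=25.0, axis=line_axis)
        occ = rasterize_shape(capillary, grid, supersample=4)
        if blur is not None:
            occ = convolve_values(occ, blur, spacing)
        return ActivityImage(grid, occ)

    @pytest.mark.parametrize("axis", [0, 1, 2])
    def test_recovers_simulated_resolution(self, axis):
        # line along a perpendicular axis; measure the blur along `axis`
        line_axis = (axis + 1) % 3
        psf = PSFModel(reference.PSF_FWHM_MM)
        image = self.line_image(line_axis, psf)
        est = estimate_fwhm(image, axis)
        assert est.fwhm_mm == pytest.approx(reference.PSF_FWHM_MM[axis], abs=0.3)
        assert not est.resolution_limited

    def test_unblurred_line_is_resolution_limited(self):
        image = self.line_image(line_axis=0, blur=None)
        est = estimate_fwhm(image, axis=1)
        assert est.fwhm_mm == pytest.approx(2.21, abs=1.2)
        assert est.resolution_limited

    def test_profile_without_half_crossing_rejected(self):
        # a small bump on a high plateau: the profile never falls below half
        grid = VoxelGrid((41, 41, 41), (2.21,) * 3)
        values = np.ones(grid.shape)
        values[20, 20, 20] = 1.1
        image = ActivityImage(grid, values)
        with pytest.raises(ValueError, match="half-maximum"):
            estimate_fwhm(image, axis=0)


class TestHeterogeneityConstruction:
    def test_added_activity_confined_to_lung_and_ratio_exact(self, iec1_run):
        image, merged = apply_background_heterogeneity(
            iec1_run.observed, iec1_run.labels, ratio=3.0
        )
        lung = iec1_run.labels.mask(LUNG_LABEL)
        diff = image.values - iec1_run.observed.values
        assert np.all(diff[~lung] == 0.0)
        assert np.all(diff[lung] > 0.0)
        merged_mask = merged.mask(BACKGROUND_LABEL)
        achieved = image.values[merged_mask].mean() / iec1_run.observed.values[merged_mask].mean()
        assert achieved == pytest.approx(3.0, rel=1e-12)
        assert LUNG_LABEL not in merged.region_ids

    def test_sub_unity_ratio_rejected(self, iec1_run):
        with pytest.raises(ValueError, match="unattainable"):
            apply_background_heterogeneity(iec1_run.observed, iec1_run.labels, ratio=0.5)


class TestBiasSvRegression:
    def test_perfect_line_has_unit_r_squared(self):
        svs = [1.5, 1.8, 2.3, 2.8]
        biases = [2.0 * s - 1.0 for s in svs]
        slope, intercept, r2 = bias_vs_sv_regression(biases, svs)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(-1.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_bias_has_zero_slope(self):
        slope, _, _ = bias_vs_sv_regression([4.0, 4.0, 4.0], [1.5, 2.0, 2.8])
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_distinct_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            bias_vs_sv_regression([1.0, 2.0], [1.5, 1.5])
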