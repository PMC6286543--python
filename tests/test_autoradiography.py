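"""Calibration fitting, inversion round trips, square-ROI means and
radial concentration profiles."""

from dataclasses import replace

import numpy as np
import numpy.testing as npt
import pandas as pd
import pytest

from batperm.autoradiography import (
    ConcentrationMap,
    fit_calibration,
    intensity_to_concentration,
    radial_concentration_profile,
    square_roi_concentration,
)
from batperm.pipelines import lesions_from_truth
from batperm.synthetic import (
    generate_autoradiograph,
    paclitaxel_step_profile,
)

from conftest import disc_mask, lesions_from_mask


def line_standards(a=5.0, b=2.0, concs=(1.0, 10.0, 50.0, 200.0)):
    return [(c, a + b * c) for c in concs]


class TestFitCalibration:
    def test_exact_line(self):
        curve = fit_calibration(line_standards(a=5.0, b=2.0))
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(5.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_duplicated_levels_accepted_with_two_distinct(self):
        curve = fit_calibration([(10.0, 25.0), (10.0, 25.0), (50.0, 105.0)])
        assert curve.n_standards == 3

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError, match="spread|range"):
            fit_calibration([(10.0, 25.0), (10.0, 25.0), (10.0, 25.0)])

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_calibration(line_standards(concs=(1.0, 10.0)))

    def test_dataframe_input(self):
        df = pd.DataFrame(
            {"concentration_ng_per_g": [1.0, 10.0, 100.0], "intensity": [7.0, 25.0, 205.0]}
        )
        assert fit_calibration(df).slope == pytest.approx(2.0)

    def test_noisy_standards_slope_bias_below_1pct(self):
        """Monte-Carlo over 100 fits: Gaussian noise (2% of range) on 6 levels."""
        rng = np.random.default_rng(0)
        concs = np.array([1.0, 5.0, 20.0, 80.0, 250.0, 700.0])
        a, b = 50.0, 20.0
        span = b * (concs.max() - concs.min())
        slopes = []
        for _ in range(100):
            y = a + b * concs + rng.normal(0, 0.02 * span, size=concs.size)
            slopes.append(fit_calibration(list(zip(concs, y))).slope)
        assert abs(np.mean(slopes) - b) / b < 0.01


class TestIntensityToConcentration:
    def test_intercept_maps_to_zero(self):
        curve = fit_calibration(line_standards(a=5.0, b=2.0))
        cmap = intensity_to_concentration(curve, np.full((4, 4), 5.0))
        npt.assert_allclose(cmap.raster, 0.0)

    def test_negative_floored_and_flagged(self):
        curve = fit_calibration(line_standards(a=5.0, b=2.0))
        cmap = intensity_to_concentration(curve, np.array([[1.0, 9.0]]))
        npt.assert_allclose(cmap.raster, [[0.0, 2.0]])
        npt.assert_array_equal(cmap.out_of_range, [[True, False]])

    def test_above_top_standard_kept_but_flagged(self):
        curve = fit_calibration(line_standards(a=0.0, b=1.0, concs=(1.0, 10.0, 100.0)))
        cmap = intensity_to_concentration(curve, np.array([[150.0]]))
        assert cmap.raster[0, 0] == pytest.approx(150.0)
        assert cmap.out_of_range[0, 0]

    def test_roundtrip_identity_noiseless(self, rng):
        a, b = 12.0, 3.5
        truth_map = rng.uniform(0, 400, size=(32, 32))
        raster = a + b * truth_map
        curve = fit_calibration([(c, a + b * c) for c in (1.0, 50.0, 500.0)])
        cmap = intensity_to_concentration(curve, raster)
        npt.assert_allclose(cmap.raster, truth_map, rtol=1e-9, atol=1e-9)


class TestSquareRoi:
    def _uniform_map(self, value=293.0, shape=(64, 64), px=5.0):
        return ConcentrationMap(
            raster=np.full(shape, value),
            pixel_size=px,
            out_of_range=np.zeros(shape, bool),
            valid_range=(0.0, 700.0),
        )

    def test_uniform_map_any_square(self):
        cmap = self._uniform_map(293.0)
        assert square_roi_concentration(cmap, (160.0, 160.0), 100.0) == 293.0
        assert square_roi_concentration(cmap, (201.0, 77.0), 50.0) == 293.0

    def test_single_pixel_square(self):
        cmap = self._uniform_map()
        cmap.raster[10, 12] = 42.0
        px = cmap.pixel_size
        assert square_roi_concentration(cmap, (10 * px, 12 * px), px) == 42.0

    def test_square_outside_raster_rejected(self):
        cmap = self._uniform_map()
        with pytest.raises(ValueError, match="outside"):
            square_roi_concentration(cmap, (0.0, 0.0), 100.0)

    def test_tiling_partition_conserves_region_mean(self, rng):
        """Tiling squares average back to the pixel-weighted region mean."""
        px, size = 5.0, 50.0  # 10x10 pixels per square
        cmap = self._uniform_map(shape=(40, 40), px=px)
        cmap.raster[:] = rng.uniform(0, 100, size=(40, 40))
        n = int(size / px)
        means, weights = [], []
        for i in range(4):
            for j in range(4):
                c = ((i * n + n / 2 - 0.5) * px, (j * n + n / 2 - 0.5) * px)
                means.append(square_roi_concentration(cmap, c, size))
                weights.append(n * n)
        assert np.average(means, weights=weights) == pytest.approx(cmap.raster.mean())


class TestRadialConcentrationProfile:
    def test_noiseless_step_levels_exact(self, noiseless_config):
        cfg = replace(noiseless_config, mirror_clearance=False, image_shape=(320, 320))
        profile = paclitaxel_step_profile()
        section, truth, standards = generate_autoradiograph(cfg, profile)
        curve = fit_calibration(standards)
        cmap = intensity_to_concentration(
            curve, section.channels["autorad"], cfg.pixel_size
        )
        lesions = lesions_from_truth(truth.lesion_labels, cfg.pixel_size)
        prof = radial_concentration_profile(cmap, lesions, 1)
        npt.assert_allclose(prof.value[prof.bin_hi <= 0], 529.0, rtol=1e-9)
        npt.assert_allclose(prof.value[prof.bin_lo == 0.0], 86.7, rtol=1e-9)
        npt.assert_allclose(prof.value[prof.bin_lo == 50.0], 35.4, rtol=1e-9)
        npt.assert_allclose(prof.value[prof.bin_lo >= 100.0], 1.0, rtol=1e-9)

    def test_affine_reexposure_invariance(self, noiseless_config):
        """Re-exposing image and standards by alpha*I + beta cancels out."""
        cfg = replace(noiseless_config, mirror_clearance=False, image_shape=(320, 320))
        section, truth, standards = generate_autoradiograph(
            cfg, paclitaxel_step_profile()
        )
        raster = section.channels["autorad"]
        lesions = lesions_from_truth(truth.lesion_labels, cfg.pixel_size)

        def run(img, stds):
            curve = fit_calibration(stds)
            cmap = intensity_to_concentration(curve, img, cfg.pixel_size)
            return radial_concentration_profile(cmap, lesions, 1).value

        alpha, beta = 1.7, 40.0
        stds2 = standards.copy()
        stds2["intensity"] = alpha * stds2["intensity"] + beta
        npt.assert_allclose(
            run(raster, standards), run(alpha * raster + beta, stds2), rtol=1e-9
        )

    def test_bat_ordering_with_noise(self):
        from batperm.synthetic import GeneratorConfig

        cfg = GeneratorConfig(image_shape=(320, 320), mirror_clearance=False, seed=5)
        section, truth, standards = generate_autoradiograph(
            cfg, paclitaxel_step_profile()
        )
        curve = fit_calibration(standards)
        cmap = intensity_to_concentration(
            curve, section.channels["autorad"], cfg.pixel_size
        )
        lesions = lesions_from_truth(truth.lesion_labels, cfg.pixel_size)
        prof = radial_concentration_profile(cmap, lesions, 1)
        bat0 = float(prof.value[prof.bin_lo == 0.0][0])
        bat50 = float(prof.value[prof.bin_lo == 50.0][0])
        distant = float(
            np.average(
                prof.value[prof.bin_lo >= 100.0],
                weights=prof.n_pixels[prof.bin_lo >= 100.0],
            )
        )
        assert bat0 > bat50 > distant
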