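"""Depletion physics, acquisition simulation, saturation fit, FRC, FWHM."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import HBMITO_IS_MW, acquire_scene, sted_settings
from mitograph.errors import EstimationError, ParameterError
from mitograph.imaging import (
    AcquisitionSettings,
    Image,
    SaturationCurveModel,
    depletion_efficiency,
    depletion_power_for_fwhm,
    effective_fwhm,
    estimate_frc_resolution,
    fit_saturation_power,
    measure_fwhm_profile,
    simulate_acquisition,
    simulate_depletion_series,
)
from mitograph.scene import DensityMap, build_tubule_grid, render_density


class TestDepletionLaw:
    @pytest.mark.parametrize(
        "power,expected",
        [(0.0, 1.0), (HBMITO_IS_MW, 0.5), (3 * HBMITO_IS_MW, 0.25)],
    )
    def test_known_points_of_the_saturation_curve(self, power, expected):
        assert depletion_efficiency(power, HBMITO_IS_MW) == pytest.approx(expected)

    def test_nonpositive_saturation_power_rejected(self):
        with pytest.raises(ParameterError):
            depletion_efficiency(1.0, 0.0)

    def test_printed_powers_give_sixfold_enhancement(self):
        factor = 250.0 / effective_fwhm(250.0, 34.7, HBMITO_IS_MW)
        assert factor == pytest.approx(np.sqrt(1 + 34.7 / HBMITO_IS_MW))
        assert factor >= 6.0

    def test_no_depletion_returns_d0_exactly(self):
        assert effective_fwhm(250.0, 0.0, HBMITO_IS_MW) == 250.0

    def test_three_is_halves_the_psf(self):
        assert effective_fwhm(250.0, 3 * HBMITO_IS_MW, HBMITO_IS_MW) == pytest.approx(125.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        lo=st.floats(0.0, 100.0),
        delta=st.floats(0.1, 100.0),
        Is=st.floats(0.1, 10.0),
    )
    def test_effective_fwhm_strictly_decreasing_in_power(self, lo, delta, Is):
        assert effective_fwhm(250.0, lo + delta, Is) < effective_fwhm(250.0, lo, Is)

    def test_power_for_target_fwhm_inverts_the_law(self):
        p = depletion_power_for_fwhm(40.0, 250.0, HBMITO_IS_MW)
        assert effective_fwhm(250.0, p, HBMITO_IS_MW) == pytest.approx(40.0)


class TestSimulateAcquisition:
    def test_zero_density_and_zero_noise_gives_zero_image(self):
        dm = DensityMap(np.zeros((64, 64)), 20.0, "IM")
        settings_ = AcquisitionSettings(photon_budget=100, background=0.0,
                                        read_noise_std=0.0)
        img = simulate_acquisition(dm, settings_, HBMITO_IS_MW, seed=0)
        assert not img.counts.any()

    def test_same_seed_is_bit_identical(self):
        scene = build_tubule_grid(2, seed=1)[0]
        a = acquire_scene(scene, "IM", sted_settings(), seed=9)
        b = acquire_scene(scene, "IM", sted_settings(), seed=9)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_point_source_profile_matches_effective_fwhm(self):
        # a single-pixel impulse imaged noise-free must show the effective PSF
        density = np.zeros((101, 101))
        density[50, 50] = 1.0
        dm = DensityMap(density, 20.0, "IM")
        settings_ = sted_settings(fwhm_nm=60.0, photon_budget=10_000)
        settings_.apply_poisson = False
        settings_.read_noise_std = 0.0
        settings_.background = 0.0
        img = simulate_acquisition(dm, settings_, HBMITO_IS_MW, seed=0)
        w = measure_fwhm_profile(img, (0.4, 1.0), (1.6, 1.0))
        assert w == pytest.approx(60.0, abs=10.0)  # within half a pixel

    def test_noise_free_acquisition_conserves_total_signal(self):
        scene = build_tubule_grid(2, seed=2)[0]
        dm = render_density(scene, "IM", 20.0)
        settings_ = sted_settings(photon_budget=500)
        settings_.apply_poisson = False
        settings_.read_noise_std = 0.0
        settings_.background = 0.0
        img = simulate_acquisition(dm, settings_, HBMITO_IS_MW, seed=0)
        # unit-mass PSF: integral preserved up to the photon-budget scale
        from scipy.ndimage import gaussian_filter

        from mitograph.imaging import FWHM_PER_SIGMA

        blurred = gaussian_filter(dm.values, (40.0 / FWHM_PER_SIGMA) / 20.0,
                                  mode="constant")
        # the PSF has unit mass, so only the photon-budget scale changes the
        # integral (tiny loss at the field edge aside)
        assert blurred.sum() == pytest.approx(dm.values.sum(), rel=1e-3)
        expected = blurred.sum() * (500.0 / blurred.max())
        assert img.counts.sum() == pytest.approx(expected, rel=1e-9)

    def test_undersampled_psf_warns(self):
        dm = DensityMap(np.ones((32, 32)), 100.0, "IM")
        s = AcquisitionSettings(I_dep_mW=34.7, d0_nm=250.0, pixel_size_nm=100.0)
        with pytest.warns(UserWarning, match="under-sampled"):
            simulate_acquisition(dm, s, HBMITO_IS_MW, seed=0)


class TestSaturationFit:
    def test_noise_free_series_recovers_printed_values_exactly(self):
        for true_is in (0.864, 3.069):
            series = simulate_depletion_series(
                true_is, np.linspace(0, 40, 12), noise_level=0.0, seed=0
            )
            res = fit_saturation_power(series)
            assert res.Is_mW == pytest.approx(true_is, rel=1e-6)
            assert res.method == "model-fit"

    def test_subtraction_recovers_half_signal_at_is(self):
        powers = np.array([0.0, HBMITO_IS_MW, 10.0, 20.0, 40.0])
        series = simulate_depletion_series(
            HBMITO_IS_MW, powers, noise_level=0.0, seed=0
        )
        diff = series.on_mean - series.off_mean
        assert diff[1] / diff[0] == pytest.approx(0.5)

    def test_recovery_unbiased_within_5pct_at_high_snr(self):
        # parameter recovery across 100 noisy series at SNR 20 (5% noise)
        est = [
            fit_saturation_power(
                simulate_depletion_series(
                    0.864, np.linspace(0, 40, 12), noise_level=0.05, seed=s
                )
            ).Is_mW
            for s in range(100)
        ]
        assert np.median(est) == pytest.approx(0.864, rel=0.05)

    def test_constant_series_is_an_error(self):
        from mitograph.imaging import SaturationSeries

        powers = np.linspace(0, 40, 6)
        series = SaturationSeries(powers, np.full(6, 5.0), np.full(6, 5.0))
        with pytest.raises(EstimationError):
            fit_saturation_power(series)

    def test_series_not_reaching_saturation_is_an_error(self):
        series = simulate_depletion_series(
            50.0, np.linspace(0, 20, 8), noise_level=0.0, seed=0
        )
        with pytest.raises(EstimationError, match="saturation"):
            fit_saturation_power(series)

    def test_too_few_powers_rejected(self):
        series = simulate_depletion_series(1.0, [0.0, 1, 2, 5], noise_level=0.0)
        with pytest.raises(ParameterError):
            SaturationCurveModel(series)

    def test_summary_mentions_method_and_estimate(self):
        series = simulate_depletion_series(0.864, np.linspace(0, 40, 12), 0.0)
        text = fit_saturation_power(series).summary()
        assert "model-fit" in text and "0.864" in text


class TestFRC:
    def test_identical_images_are_flagged_as_nyquist_bound(self, network_scene):
        img = acquire_scene(network_scene, "IM", sted_settings(), seed=1)
        res = estimate_frc_resolution(img, img)
        assert res.is_bound
        assert res.resolution_nm == pytest.approx(2 * img.pixel_size_nm)

    def test_pure_noise_reports_no_resolution(self):
        rng = np.random.default_rng(0)
        a = Image(rng.poisson(5.0, (256, 256)).astype(float), 20.0)
        b = Image(rng.poisson(5.0, (256, 256)).astype(float), 20.0)
        res = estimate_frc_resolution(a, b)
        assert res.no_correlation
        assert np.isnan(res.resolution_nm)

    def test_resolution_degrades_as_photons_decrease(self, network_scene):
        values = []
        for budget in (1000.0, 120.0, 30.0):
            a = acquire_scene(network_scene, "IM",
                              sted_settings(photon_budget=budget), seed=1)
            b = acquire_scene(network_scene, "IM",
                              sted_settings(photon_budget=budget), seed=2)
            res = estimate_frc_resolution(a, b)
            assert not res.no_correlation
            values.append(res.resolution_nm)
        assert values[0] <= values[1] <= values[2]

    def test_mismatched_shapes_rejected(self):
        a = Image(np.zeros((32, 32)), 20.0)
        b = Image(np.zeros((16, 16)), 20.0)
        with pytest.raises(ParameterError):
            estimate_frc_resolution(a, b)


class TestFWHMProfile:
    def test_analytic_gaussian_ridge_recovered_within_one_percent(self):
        yy, xx = np.indices((100, 200))
        sigma_px = 3.0
        ridge = 100.0 * np.exp(-0.5 * ((xx - 100) / sigma_px) ** 2)
        img = Image(ridge, 20.0)
        w = measure_fwhm_profile(img, (1.0, 1.0), (3.0, 1.0))
        assert w == pytest.approx(2.3548 * sigma_px * 20.0, rel=0.01)

    def test_flat_profile_is_an_error(self):
        img = Image(np.full((50, 50), 7.0), 20.0)
        with pytest.raises(EstimationError):
            measure_fwhm_profile(img, (0.1, 0.5), (0.9, 0.5))

    def test_line_outside_image_rejected(self):
        img = Image(np.zeros((50, 50)), 20.0)
        with pytest.raises(ParameterError):
            measure_fwhm_profile(img, (0.0, 0.0), (5.0, 5.0))
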