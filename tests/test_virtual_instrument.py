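"""Forward model: rendering physics, noise model, and closed-form oracles."""

import math

import numpy as np
import pytest

from openivis.core import AcquisitionSetting
from openivis.virtual_instrument import (
    CameraModel,
    LedChannel,
    LedModel,
    clipped_normal_moments,
    clipped_normal_params,
    dark_stack,
    presets,
    radial_vignetting,
    render,
    render_sweep,
)

BLUE = "blue_460"


def plate_scene(conc=1e-6, k=1e8, eps_l=0.0):
    from openivis.platequant import PlateLayout
    from openivis.virtual_instrument import FluorophoreModel, PlateScene

    layout = PlateLayout(n_rows=2, n_cols=3, pitch_px=30, well_radius_px=10,
                         origin_px=(20, 20))
    fluor = FluorophoreModel(
        excitation={BLUE: 1.0},
        emission=[(530.0, 1.0)],
        brightness_k=k,
        eps_l=eps_l,
    )
    concs = {layout.label(r, c): conc for r in range(2) for c in range(3)}
    return PlateScene(layout=layout, concentrations=concs, fluorophore=fluor)


def setting(exposure=10.0, drive=1.0, cuton=None):
    return AcquisitionSetting(exposure_ms=exposure, led_channel=BLUE,
                              drive_level=drive, filter_cuton_nm=cuton)


class TestRender:
    def test_noise_free_render_is_reproducible(self, ideal_camera):
        scene = plate_scene()
        f1 = render(scene, setting(), ideal_camera, seed=0)
        f2 = render(scene, setting(), ideal_camera, seed=12345)
        assert np.array_equal(f1.pixels, f2.pixels)

    def test_noisy_render_reproducible_given_seed(self):
        cam = CameraModel(read_noise_sd=np.full(3, 2.0), shot_noise=True)
        scene = plate_scene()
        f1 = render(scene, setting(), cam, seed=7)
        f2 = render(scene, setting(), cam, seed=7)
        f3 = render(scene, setting(), cam, seed=8)
        assert np.array_equal(f1.pixels, f2.pixels)
        assert not np.array_equal(f1.pixels, f3.pixels)

    def test_short_exposure_limit_equals_black_level(self):
        cam = CameraModel(black_level=np.array([1.0, 2.0, 3.0]))
        scene = plate_scene(k=1e-12)
        frame = render(scene, setting(exposure=1e-9), cam, seed=0)
        assert np.allclose(frame.pixels, cam.black_level, atol=1e-9)

    def test_exposure_linearity_before_saturation(self, ideal_camera):
        scene = plate_scene(k=1e6)  # dim enough to stay unsaturated
        f1 = render(scene, setting(exposure=5.0), ideal_camera, seed=0)
        f2 = render(scene, setting(exposure=10.0), ideal_camera, seed=0)
        assert f2.pixels.max() < f2.saturation
        assert f2.pixels.max() > 1.0
        assert np.allclose(f2.pixels, 2.0 * f1.pixels, rtol=1e-12)

    def test_saturating_concentration_clips_to_full_scale(self, ideal_camera):
        scene = plate_scene(conc=1.0, k=1e8)
        frame = render(scene, setting(), ideal_camera, seed=0)
        well_px = frame.pixels[20, 20]
        assert np.all(well_px == frame.saturation)

    def test_drive_monotonicity(self, ideal_camera):
        scene = plate_scene()
        lows = render(scene, setting(drive=0.3), ideal_camera, seed=0).pixels
        highs = render(scene, setting(drive=0.9), ideal_camera, seed=0).pixels
        assert np.all(highs >= lows)

    def test_longpass_consistency(self, ideal_camera):
        # lower cut-on can only pass more of the emission
        from openivis.virtual_instrument import FluorophoreModel, MineralRegion, MineralScene

        scene = MineralScene(
            regions=[MineralRegion("m", (5, 5, 25, 25),
                                   [(500.0, 0.4), (600.0, 0.6)], 1.0)],
            shape=(40, 40),
        )
        s_lo = AcquisitionSetting(exposure_ms=50, led_channel="external_uv",
                                  filter_cuton_nm=450.0)
        s_hi = AcquisitionSetting(exposure_ms=50, led_channel="external_uv",
                                  filter_cuton_nm=550.0)
        lo = render(scene, s_lo, ideal_camera, seed=0).pixels
        hi = render(scene, s_hi, ideal_camera, seed=0).pixels
        assert np.all(lo >= hi)


class TestSweep:
    def test_single_setting_stack_of_one(self, ideal_camera):
        stack = render_sweep(plate_scene(), [setting()], ideal_camera, seed=0)
        assert len(stack) == 1

    def test_means_increase_with_exposure_until_saturation(self, ideal_camera):
        scene = plate_scene()
        stack = render_sweep(
            scene, [setting(exposure=t) for t in (1.0, 10.0, 100.0)],
            ideal_camera, seed=0,
        )
        well_means = [f.pixels[20, 20, 1] for f in stack]
        unsaturated = [m for m in well_means if m < stack[0].saturation]
        assert np.all(np.diff(unsaturated) > 0)

    def test_empty_settings_error(self, ideal_camera):
        with pytest.raises(ValueError):
            render_sweep(plate_scene(), [], ideal_camera, seed=0)


class TestSaturationFactor:
    def test_f_sat_approaches_one_at_low_concentration(self):
        fluor = presets.fitc()
        # series expansion check at eps_l * c = 1e-6
        c = 1e-6 / fluor.eps_l
        u = 1e-6 * math.log(10)
        expected = 1.0 - u / 2.0 + u**2 / 6.0
        assert fluor.f_sat(c) == pytest.approx(expected, rel=1e-4)

    def test_f_sat_strictly_decreasing(self):
        fluor = presets.fitc()
        concs = np.logspace(-12, -2, 30)
        vals = fluor.f_sat(concs)
        assert np.all(np.diff(vals) < 0)

    def test_f_sat_known_value(self):
        # closed form: (1 - 10**-q) / (q ln 10) at q = 1
        fluor = presets.fitc()
        c = 1.0 / fluor.eps_l
        expected = (1 - 0.1) / math.log(10)
        assert fluor.f_sat(c) == pytest.approx(expected, rel=1e-12)


class TestDarkStack:
    def test_zero_noise_gives_exact_black_level(self):
        cam = CameraModel(black_level=np.array([1.0, 2.0, 3.0]))
        stack = dark_stack(cam, 3, 8, 8, seed=0)
        for f in stack:
            assert np.allclose(f.pixels, [1.0, 2.0, 3.0])

    def test_zero_mean_noise_clips_at_zero(self):
        cam = CameraModel(black_level=np.zeros(3), read_noise_sd=np.full(3, 5.0))
        stack = dark_stack(cam, 2, 32, 32, seed=0)
        assert all(np.all(f.pixels >= 0) for f in stack)
        assert any(np.any(f.pixels == 0) for f in stack)  # clipping active

    def test_monte_carlo_matches_closed_form_clipped_moments(self):
        mu, sigma = -0.5, 1.4
        cam = CameraModel(black_level=np.full(3, mu), read_noise_sd=np.full(3, sigma))
        stack = dark_stack(cam, 6, 300, 300, seed=3)
        from openivis.core import stack_mean_std

        means, stds = stack_mean_std(stack)
        m_exp, s_exp = clipped_normal_moments(mu, sigma)
        # 1.6e6 samples: Monte-Carlo error well below 0.02 counts
        assert np.allclose(means, m_exp, atol=0.02)
        assert np.allclose(stds, s_exp, atol=0.02)


class TestClippedNormalInversion:
    @pytest.mark.parametrize("mean,sd", [(0.50, 0.84), (0.36, 0.68), (0.57, 0.87), (5.0, 1.0)])
    def test_roundtrip(self, mean, sd):
        mu, sigma = clipped_normal_params(mean, sd)
        m, s = clipped_normal_moments(mu, sigma)
        assert m == pytest.approx(mean, abs=1e-9)
        assert s == pytest.approx(sd, abs=1e-9)

    def test_invalid_observations_rejected(self):
        with pytest.raises(ValueError):
            clipped_normal_params(-1.0, 1.0)


class TestModels:
    def test_led_power_must_vanish_at_zero_drive(self):
        with pytest.raises(ValueError):
            LedChannel(460.0, lambda d: d + 0.1, lambda x: 1.0)

    def test_led_power_must_be_monotone(self):
        with pytest.raises(ValueError):
            LedChannel(460.0, lambda d: math.sin(6 * d), lambda x: 1.0)

    def test_external_channel_has_unit_power(self):
        led = LedModel.default()
        assert led.relative_power("external_uv", 0.7) == 1.0
        assert led.relative_power("off", 1.0) == 0.0

    def test_vignetting_field_range(self):
        field = radial_vignetting((51, 71), 0.02)
        assert field.max() == pytest.approx(1.0, abs=1e-6)
        assert field.min() == pytest.approx(0.98, abs=1e-9)

    def test_emission_weights_validated(self):
        from openivis.virtual_instrument import FluorophoreModel

        with pytest.raises(ValueError):
            FluorophoreModel(excitation={}, emission=[(500.0, 0.5)], brightness_k=1.0)
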