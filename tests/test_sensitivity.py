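"""Dose-response curves, LOD with brute-force oracle, dynamic range, 4PL."""

import numpy as np
import pytest

from openivis.platequant import detect_grid
from openivis.sensitivity import (
    Fit4PL,
    ResponseCurve,
    _logistic4,
    build_curves,
    detection_limit,
    dynamic_range,
    normalize,
    recommend_exposure,
    sensor_calibration,
)
from openivis.virtual_instrument import presets, render_sweep


def curve_from_arrays(concs, exposures, means, blank_means, blank_sds, sat=255.0):
    means = np.asarray(means, dtype=float)
    return ResponseCurve(
        concentrations=np.asarray(concs, dtype=float),
        exposures_ms=np.asarray(exposures, dtype=float),
        means=means,
        sds=np.zeros_like(means),
        ns=np.full(means.shape, 3, dtype=int),
        blank_means=np.asarray(blank_means, dtype=float),
        blank_sds=np.asarray(blank_sds, dtype=float),
        blank_n=8,
        saturation=sat,
    )


@pytest.fixture(scope="module")
def dilution_curve():
    scene, plate_map, camera, settings = presets.fitc_dilution()
    stack = render_sweep(scene, settings, camera, seed=5)
    grid = detect_grid(stack[-1], scene.layout)
    return build_curves(stack, grid, plate_map)


class TestBuildCurves:
    def test_replicates_and_series_bookkeeping(self, dilution_curve):
        curve = dilution_curve
        assert curve.means.shape == (6, 10)  # 6 exposures x 10 concentrations
        assert np.all(curve.ns == 3)  # triplicate wells
        assert curve.blank_n == 10
        assert np.all(np.diff(curve.concentrations) < 0)

    def test_noise_free_curve_matches_forward_model(self, ideal_camera):
        from openivis.core import GRAY_WEIGHTS
        from openivis.virtual_instrument import LedModel

        scene, plate_map, _, settings = presets.fitc_dilution()
        stack = render_sweep(scene, settings[:2], ideal_camera, seed=0)
        grid = detect_grid(stack[-1], scene.layout)
        curve = build_curves(stack, grid, plate_map, background="none")
        led = LedModel.default()
        for ei, setting in enumerate(settings[:2]):
            for ci, conc in enumerate(curve.concentrations):
                truth = float(
                    scene.fluorophore.well_rate(conc, setting, ideal_camera, led)
                    @ GRAY_WEIGHTS * setting.exposure_ms
                )
                truth = min(truth, ideal_camera.saturation)
                measured = curve.means[ei, ci]
                if truth > 0.5:  # skip sub-quantization signals
                    assert measured == pytest.approx(truth, rel=0.01)
                assert curve.sds[ei, ci] == pytest.approx(0.0, abs=1e-9)

    def test_missing_blanks_rejected(self, dilution_curve):
        scene, plate_map, camera, settings = presets.fitc_dilution()
        stack = render_sweep(scene, settings[:1], camera, seed=0)
        grid = detect_grid(stack[0], scene.layout)
        no_blanks = {k: v for k, v in plate_map.items() if v > 0}
        with pytest.raises(ValueError, match="blank"):
            build_curves(stack, grid, no_blanks)


class TestNormalize:
    def test_max_mode(self):
        c = curve_from_arrays([1e-3, 1e-4, 1e-5], [10.0], [[8.0, 4.0, 2.0]], [0.0], [0.0])
        n = normalize(c, "max")
        assert np.allclose(n.means[0], [1.0, 0.5, 0.25])
        assert n.means[0].max() == 1.0

    def test_minmax_mode(self):
        c = curve_from_arrays([1e-3, 1e-4, 1e-5], [10.0], [[8.0, 4.0, 2.0]], [0.0], [0.0])
        n = normalize(c, "minmax")
        assert np.allclose(n.means[0], [1.0, 1.0 / 3.0, 0.0])

    def test_max_preserves_ordering(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(1, 200, 10)
        c = curve_from_arrays(np.sort(vals)[::-1] * 1e-6, [1.0], [vals], [0.0], [0.0])
        n = normalize(c, "max")
        assert np.array_equal(np.argsort(n.means[0]), np.argsort(vals))

    def test_constant_series_minmax_errors(self):
        c = curve_from_arrays([1e-3, 1e-4], [1.0], [[5.0, 5.0]], [0.0], [0.0])
        with pytest.raises(ValueError):
            normalize(c, "minmax")


def brute_force_lod(curve, k):
    """Exhaustive oracle: scan every (exposure, concentration) outcome."""
    concs = curve.concentrations  # decreasing
    detected_any = []
    for ci in range(len(concs)):
        hit = False
        for ei in range(len(curve.exposures_ms)):
            thr = curve.blank_means[ei] + k * curve.blank_sds[ei]
            if curve.means[ei, ci] > thr:
                hit = True
        detected_any.append(hit)
    lod = None
    for ci, hit in enumerate(detected_any):
        if hit:
            lod = concs[ci]
        else:
            break
    return lod


class TestDetectionLimit:
    def test_threshold_arithmetic(self):
        c = curve_from_arrays([1e-9, 1e-10], [1.0], [[14.0, 12.0]], [10.0], [1.0])
        res = detection_limit(c, k=3.0)
        assert res.threshold_counts == pytest.approx(13.0)
        assert res.lod_molar == pytest.approx(1e-9)

    def test_nothing_detected(self):
        c = curve_from_arrays([1e-9, 1e-10], [1.0], [[1.0, 1.0]], [10.0], [1.0])
        res = detection_limit(c)
        assert not res.detectable

    def test_monotone_closure_discards_isolated_detection(self):
        # middle concentration undetected: the detection below it is discarded
        c = curve_from_arrays(
            [1e-8, 1e-9, 1e-10], [1.0], [[20.0, 5.0, 20.0]], [10.0], [1.0]
        )
        res = detection_limit(c, k=3.0)
        assert res.lod_molar == pytest.approx(1e-8)

    def test_lod_never_increases_when_k_decreases(self, dilution_curve):
        lods = []
        for k in (5.0, 3.0, 1.0):
            res = detection_limit(dilution_curve, k=k)
            lods.append(res.lod_molar if res.detectable else np.inf)
        assert lods[1] <= lods[0] and lods[2] <= lods[1]

    def test_agrees_with_brute_force_oracle_on_random_grids(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n_c = rng.integers(2, 10)
            n_e = rng.integers(1, 10)
            concs = np.sort(rng.uniform(1e-12, 1e-3, n_c))[::-1]
            means = rng.uniform(0, 30, (n_e, n_c))
            bm = rng.uniform(0, 10, n_e)
            bs = rng.uniform(0, 3, n_e)
            c = curve_from_arrays(concs, np.arange(1, n_e + 1), means, bm, bs)
            res = detection_limit(c, k=3.0)
            expected = brute_force_lod(c, 3.0)
            if expected is None:
                assert not res.detectable
            else:
                assert res.lod_molar == pytest.approx(expected)

    def test_reference_sweep_reaches_10_picomolar(self, dilution_curve):
        res = detection_limit(dilution_curve, k=3.0)
        assert res.detectable
        assert res.lod_molar <= 1e-11  # 10 pM


class TestDynamicRange:
    def test_all_saturated_is_empty(self):
        c = curve_from_arrays([1e-3, 1e-4], [1.0], [[255.0, 255.0]], [0.1], [0.01])
        assert dynamic_range(c, 1.0).empty

    def test_four_decades_linear_series(self):
        concs = [1e-5, 1e-6, 1e-7, 1e-8, 1e-9]
        means = [[100.0, 10.0, 1.0, 0.1, 0.01]]
        c = curve_from_arrays(concs, [1.0], means, [0.001], [0.001])
        dr = dynamic_range(c, 1.0)
        assert dr.lowest_molar == pytest.approx(1e-9)
        assert dr.highest_molar == pytest.approx(1e-5)
        assert dr.decades == pytest.approx(4.0)

    def test_longer_exposure_lowers_detection_floor(self, dilution_curve):
        lows = []
        for exp in (10.0, 1000.0):
            dr = dynamic_range(dilution_curve, exp)
            lows.append(dr.lowest_molar)
        assert lows[1] <= lows[0]


class TestRecommendExposure:
    def test_single_exposure_curve(self):
        c = curve_from_arrays([1e-4, 1e-5], [7.0], [[50.0, 5.0]], [0.1], [0.01])
        assert recommend_exposure(c, (1e-5, 1e-4)) == 7.0

    def test_longer_wins_when_it_covers_both_targets(self):
        # short exposure leaves the dim target below threshold
        c = curve_from_arrays(
            [1e-4, 1e-5],
            [1.0, 100.0],
            [[10.0, 0.05], [100.0, 10.0]],
            [0.02, 0.02],
            [0.01, 0.01],
        )
        assert recommend_exposure(c, (1e-5, 1e-4)) == 100.0

    def test_tie_broken_by_shorter_exposure(self):
        c = curve_from_arrays(
            [1e-4, 1e-5],
            [1.0, 100.0],
            [[50.0, 5.0], [150.0, 60.0]],
            [0.02, 0.02],
            [0.01, 0.01],
        )
        assert recommend_exposure(c, (1e-5, 1e-4)) == 1.0

    def test_no_coverage_errors(self):
        c = curve_from_arrays([1e-4, 1e-5], [1.0], [[255.0, 0.0]], [0.1], [0.01])
        with pytest.raises(ValueError):
            recommend_exposure(c, (1e-5, 1e-4))


class TestSensorCalibration:
    def make_4pl_curve(self, bottom=0.0, top=1.0, ec50=1e-3, slope=1.0, n=9):
        concs = np.logspace(-6, 0, n)[::-1]
        y = _logistic4(np.log10(concs), bottom, top, np.log10(ec50), slope)
        return curve_from_arrays(concs, [80.0], [y], [0.0], [0.0])

    def test_parameters_recovered_within_one_percent(self):
        c = self.make_4pl_curve(bottom=0.0, top=1.0, ec50=1e-3, slope=1.0)
        fit = sensor_calibration(c)
        assert fit.bottom == pytest.approx(0.0, abs=1e-4)
        assert fit.top == pytest.approx(1.0, rel=0.01)
        assert fit.ec50_molar == pytest.approx(1e-3, rel=0.01)
        assert fit.slope == pytest.approx(1.0, rel=0.01)
        assert fit.r_squared > 0.9999

    def test_decreasing_response_gives_negative_slope(self):
        c = self.make_4pl_curve(bottom=1.0, top=0.0, ec50=1e-3, slope=1.0)
        fit = sensor_calibration(c)
        assert fit.slope < 0 or fit.top < fit.bottom

    def test_flat_series_rejected(self):
        c = curve_from_arrays(np.logspace(-6, -1, 6)[::-1], [1.0],
                              [np.full(6, 0.5)], [0.0], [0.0])
        with pytest.raises(ValueError):
            sensor_calibration(c)

    def test_too_few_concentrations_rejected(self):
        c = curve_from_arrays([1e-3, 1e-4, 1e-5], [1.0], [[1.0, 0.5, 0.0]], [0.0], [0.0])
        with pytest.raises(ValueError):
            sensor_calibration(c)

    def test_predict_roundtrip(self):
        fit = Fit4PL(bottom=0.0, top=1.0, ec50_molar=1e-3, slope=1.0, r_squared=1.0)
        assert fit.predict(1e-3) == pytest.approx(0.5)
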