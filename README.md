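# openivis

A **virtual LED-excitation fluorescence imaging box** plus the calibration
and quantification procedures used to characterize and apply one.

Low-cost enclosed imaging boxes — a color camera looking down at a sample
stage, RGB LED excitation modules, and swappable long-pass/bandpass emission
filters — are increasingly used for fluorescence work: well-plate assays,
DNA gel imaging, mineral fluorescence, plant-stress indices, and small-animal
time-lapse. This package provides

1. a physically parameterized **forward model** (`openivis.virtual_instrument`)
   that renders 8/16-bit RGB frames in detector counts from scene
   descriptions (96-well plates, agarose gels, 1951 USAF / color-checker /
   grid targets, fluorescent minerals, growing specimens) under models of the
   LEDs, ideal step filters, fluorophores, and the camera; and
2. the **analysis procedures** a user of such an instrument runs against it:
   dark-frame black level, CIE76 color accuracy, radial distortion, LED
   linearity, USAF resolution (`calibration`), well-grid detection, per-well
   statistics, flatness and flat-field correction (`platequant`),
   exposure-sweep dose–response, limit of detection and 4PL sensor
   calibration (`sensitivity`), gel lane densitometry (`geldens`), long-pass
   filter-series spectral reconstruction and the anthocyanin index
   (`spectral`), and time-lapse growth tracking (`timelapse`).

The forward model doubles as the synthetic-data backbone for the test suite:
every analysis is validated by recovering parameters that were injected at
render time.

## The pixel model

For a fluorophore at molar concentration *c*, imaged for *t* ms:

```
counts = clip( black + gain · signal + read_noise , 0, 2^bits − 1 )

signal = k · c · f_sat(c) · excitation(drive) · emission→channel · t · field(x, y)

f_sat(c) = (1 − 10^(−εl·c)) / (εl·c · ln 10)          (→ 1 as c → 0)
```

`k` is a brightness constant (counts·M⁻¹·ms⁻¹), `f_sat` an inner-filter-style
saturation giving the high-concentration roll-off, `emission→channel`
distributes the filtered discrete emission lines over R, G, B by the camera's
spectral response, and `field` is the illumination flatness (e.g. radial
vignetting). Shot noise, when enabled, draws the signal from a Poisson law.
Dark frames are zero-clipped Gaussians; the closed-form clipped-normal
moments (and their numerical inversion) live in `virtual_instrument`.

Key derived quantities follow the field's standard definitions: USAF element
frequency `2^(group + (element−1)/6)` lp/mm with Michelson contrast
`(Imax−Imin)/(Imax+Imin)`; line width `500/f` μm; per-well percent deviation
`100·(vᵢ−v̄)/v̄`; LOD = smallest concentration exceeding `blank + 3·SD`
(monotone closure over the dilution series, best over exposures); gel
migration `position = a − b·log10(bp)`; growth rate = slope of `ln(area)` vs
time.

## Worked example

```python
from openivis import calibration, platequant, sensitivity
from openivis.virtual_instrument import presets, render, render_sweep

# optical resolution from a blurred synthetic 1951 USAF target
scene = presets.usaf_target(scale_px_per_mm=100.0, blur_sigma_um=30.0)
frame = render(scene, presets.fitc_setting(100.0), presets.ideal_camera(), seed=0)
freq, elem, _ = calibration.usaf_resolution(frame, scene.usaf_rois(),
                                            contrast_threshold=0.1)
print(f"finest resolvable: {freq:.2f} lp/mm (group {elem.group}, "
      f"element {elem.element}) -> {calibration.lp_per_mm_to_um(freq):.1f} um lines")

# flatness of a uniform 10 uM plate with 2% vignetting, per-well SNR 200
scene, camera, setting = presets.flatness_plate()
plate = render(scene, setting, camera, seed=1)
grid = platequant.detect_grid(plate, scene.layout)
values, _ = platequant.well_intensities(plate, grid)
_, max_dev = platequant.percent_deviation(values)
print(f"flatness: max |deviation| = {max_dev:.2f}% across 96 wells")

# limit of detection of a 10-decade dilution series over a 1-10000 ms sweep
scene, plate_map, camera, settings = presets.fitc_dilution()
stack = render_sweep(scene, settings, camera, seed=1)
grid = platequant.detect_grid(stack[-1], scene.layout)
curve = sensitivity.build_curves(stack, grid, plate_map)
lod = sensitivity.detection_limit(curve, k=3.0)
print(f"LOD: {lod.lod_molar*1e12:.0f} pM (first reached at {lod.exposure_ms:.0f} ms)")
```

prints

```
finest resolvable: 11.31 lp/mm (group 3, element 4) -> 44.2 um lines
flatness: max |deviation| = 1.22% across 96 wells
LOD: 1 pM (first reached at 10 ms exposure)
```

The resolution sits two elements above the 7 lp/mm (70 μm) benchmark for a
30 μm blur kernel — consistent with the square-wave attenuation
`(4/π)·exp(−2π²σ²f²)` crossing the 0.1 contrast threshold near 12 lp/mm. The
flatness stays inside the ±3% band expected from 2% vignetting plus
SNR-200 well noise, and the dilution sweep reaches picomolar detection at
long exposures while millimolar wells saturate — the exposure-time trade-off
that gives the instrument its multi-decade dynamic range.

A CLI mirrors the workflows (`openivis simulate|calibrate|plate|sweep|gel|
spectral|anthocyanin|timelapse`); run `openivis --help`.

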