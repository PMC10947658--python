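# Methods

This note documents the models, defaults, and numerical choices behind the
package, and what the synthetic scenes do and do not emulate.

## Forward model

**Pixel pipeline.** Every scene produces an expected per-channel signal rate
(counts·ms⁻¹ at gain 1) per pixel; rendering multiplies by the exposure,
optionally Poisson-samples the signal (shot noise), applies the gain, adds
the per-channel black-level offset and Gaussian read noise, and clips to
`[0, 2^bits − 1]`. Images are processed as float counts throughout;
quantization happens only at file write (PNG/TIFF). Default bit depth is 8
(the common PNG acquisition path); 16-bit is supported for headroom studies.

**Fluorophores.** An emitter is excitation efficiencies per LED channel, a
discrete line emission spectrum (weights sum to 1), a brightness constant
`k` (counts·M⁻¹·ms⁻¹ at unit drive and gain), and an inner-filter product
`εl` (M⁻¹). The concentration response is `k·c·f_sat(c)` with
`f_sat(c) = (1 − 10^(−εl·c))/(εl·c·ln10)`: the fraction-of-light-absorbed
form that rolls off smoothly at high concentration without modelling
quenching — a phenomenological stand-in for the flattening seen in real
dilution series. `f_sat` is strictly decreasing and → 1 as c → 0; below
`u = εl·c·ln10 = 10⁻⁶` a 3-term series is used for numerical stability.

**Filters and LEDs.** Emission filters are ideal steps (long-pass: transmit
λ ≥ cut-on; bandpass: transmit |λ − center| ≤ halfwidth). Together with
discrete emission lines this keeps spectral reconstruction testable in
closed form, at the cost of ignoring real transition slopes. The LED model
maps drive ∈ [0,1] to relative power (default linear, validated monotone
with zero power at zero drive) and distance to irradiance (default
inverse-square). The three RGB channels peak at 460, 520, 630 nm; the
red channel is sometimes quoted as 620 nm in datasheets — treated as the
same 630 nm channel. Externally driven sources (UV lamps under manual
control) render at unit relative power.

**Camera.** Per-channel spectral response defaults to Gaussians centered at
600/540/465 nm (R/G/B) — a generic color-camera CFA, not a measured curve.
The black level is the *underlying* offset and may be negative: observable
dark statistics arise from zero-clipping of the read noise. Closed-form
clipped-normal moments and their numerical inversion
(`clipped_normal_moments` / `clipped_normal_params`, solved with
`scipy.optimize.root`) let a camera be moment-matched to measured dark-frame
mean/std; saturation clipping is negligible at dark levels and is ignored in
the moment equations (it is applied in the generator).

**Dark-frame statistics** are pooled over space and frames (the natural
reading of "mean across the full resolution over a series of images");
per-pixel temporal statistics are not separately reported.

**Seeds.** Every stochastic operation takes an explicit integer seed;
sweeps and series derive per-frame seeds as `seed + index`. Noise-free
renders are bit-reproducible regardless of seed.

## Scenes and what they emulate

* **PlateScene** — 96-well lattice (8×12, 40 px pitch, 14 px well radius by
  default) of uniform disks, multiplied by an illumination field (default: a
  radial vignetting `1 − a·(r/r_corner)²`). Real plates have menisci, edge
  reflections, and partial-fill variation that are not modelled; the well
  statistic (mean over a 0.8-radius disk) is chosen to be insensitive to
  those effects on real data too.
* **GelScene** — Gaussian bands on a semilog migration model
  `position = a − b·log10(bp)` (defaults a = 625 px, b = 150 px/decade,
  σ = 3 px: below half the tightest 1 kb-ladder band spacing of ~8.7 px).
  Band amplitude scales with lane load; per-band mass weighting, smile, and
  diffusion broadening with size are not modelled.
* **TargetScene** — 1951 USAF three-bar elements (vertical bars, groups 0–3
  by default, antialiased by analytic pixel coverage), the classic 24-patch
  color checker, or a line grid. Optical blur is an isotropic Gaussian
  (σ in μm at the sample plane); lens geometry is a single radial term
  `r' = r(1 + k1·r²)` about the image center. Targets render as reflective
  charts under full-spectrum light — the LED spectral model is bypassed.
* **MineralScene / SpecimenScene** — boxed regions with line emission
  spectra; a bright ellipse growing over days (area × e^(g·t), default
  g = 0.3 day⁻¹ over 10 days — a plausible larval growth rate chosen once
  for the preset; only qualitative monotonicity is asserted against it).

## Analysis procedures: defaults and numerics

* **Black level**: flag "calibration needed" if any channel mean exceeds
  1.0 counts (default threshold).
* **Color accuracy**: CIE76 ΔE after sRGB→Lab (D65). CIEDE2000 would weight
  chroma more perceptually; CIE76 is kept for transparency and because the
  check is a closeness assertion, not a perceptual ranking.
* **Distortion**: grid crossings detected by combining directional minimum
  filters (a crossing is dark along both axes); the ideal lattice is fitted
  to near-center crossings where distortion is negligible, then
  `r' = α·ρ + β·ρ³` is solved linearly for spacing and k1. |k1| < 10⁻⁸ px⁻²
  classifies as "none"; recovery of injected k1 is reliable once
  `|k1|·r_max² ≳ 10⁻³`. Higher-order radial terms and tangential distortion
  are out of scope.
* **USAF resolution**: per element, a profile from the first to the third
  bar center (crossing exactly two gaps), Michelson contrast, scan coarse →
  fine, stop at the first element below the 0.1 threshold (a Rayleigh-like
  convention; no standard value exists, so it is a parameter). The blurred-
  target expectation follows the square-wave fundamental attenuation
  `(4/π)e^(−2π²σ²f²)`.
* **LED linearity**: OLS with R²; a zero-variance response reports slope 0
  and R² = 0 with a warning rather than raising.
* **Grid detection**: given a layout, lattice centers are refined by an
  iterated local intensity centroid (window 0.45·pitch — it must straddle
  the well edge; shifts capped at pitch/4). Without a layout, the pitch is
  the *first* significant autocorrelation peak (not the strongest — that can
  be a harmonic) and the phase a grid search over a well-averaged deviation
  image. Wells without local contrast (< 1 count vs. surround) keep nominal
  centers; "grid not found" means almost no wells have contrast or
  refinement diverges on > 10% of those that do.
* **Well statistics**: mean over a disk of 0.8 × well radius; optional
  background = median of a 1.2–1.5 r annulus, subtracted and floored at 0.
  Flatness uses raw values (background "none"); dilution analysis defaults
  to annulus subtraction. Percent deviation is about the plate mean and sums
  to zero by construction; the flatness figure of merit is the *max*
  absolute deviation (the conservative reading of a ±bound).
* **LOD**: blank + k·SD (k = 3 default) per exposure; a concentration counts
  as detected at any exposure; monotone closure discards isolated
  detections below an undetected concentration. Dynamic range uses a 0.9 ×
  full-scale saturation guard; the exposure recommendation maximizes the
  count of target concentrations inside [threshold, 0.9·saturation], ties to
  the shorter exposure — one defensible formalization of "best dynamic
  range for the concentrations of interest".
* **4PL calibration**: `y = bot + (top−bot)/(1 + 10^((logEC50 − logc)·s))`,
  initialized from the series min/max, half-crossing, and trend sign; fitted
  with `scipy.optimize.curve_fit`.
* **Gel densitometry**: per-row lane means; rolling-minimum background
  (window 50 px) floored at 0, raw mode available; bands = peaks with
  prominence ≥ 5% of range, areas integrated trapezoidally between flanking
  minima; lane matching is greedy nearest within 5 px.
* **Spectral series**: long-pass responses are repaired to nonincreasing by
  isotonic regression (noise will violate monotonicity on real data;
  repairing and flagging beats raising). Band energies are successive
  differences, floored at 0, with an open-ended terminal band; they
  telescope to the first cut-on's signal exactly on monotone input.
* **Anthocyanin index**: `ln((F_red_exc + ε)/(F_green_exc + ε))`, ε = 0.5
  counts, both frames through the same long-pass filter. The plant-stress
  literature has several index variants built on this excitation-ratio idea;
  the exact published variant is not uniquely determined, so the formula is
  documented and pluggable.
* **Growth tracking**: Otsu on gray, holes filled, largest component;
  exponential (log-linear) fit by default with a linear option; 95% CI from
  the residual variance; frames failing segmentation are excluded with a
  warning.

## Flatness-plate noise calibration

"Per-well SNR 200" is implemented as the SNR of the well statistic: the
well-mean signal divided by the standard error of the disk mean. The preset
sizes the per-pixel read noise so that shot noise (at gain 1) plus read
noise pooled over the ~394-pixel measurement disk gives exactly that SNR at
the target well level (~180 counts gray at 10 ms). Under these conditions
2% vignetting contributes ~±1.4% well-to-well spread and noise ~0.5% per
well, so the maximum absolute deviation across 96 wells sits comfortably
inside ±3%.

## Problem sizes

The shipped presets use a 360×520 px plate image (96 wells), a ~1320×600 px
USAF chart (24 elements, groups 0–3 at 100 px/mm), a 1000×1000 px
19×19-crossing grid chart, a ~670×320 px 4-lane gel, 60–240 px mineral and
specimen frames, and 10 frames of 1000×1000 for dark-frame statistics —
sizes at which every analysis is exercised end-to-end in seconds while
keeping estimator errors (e.g. Monte-Carlo error of the dark mean,
~3·10⁻⁴ counts) far below the tolerances being tested.

## What passing tests do and do not show

The synthetic scenes are idealized: step filters, line spectra, flat wells,
Gaussian optics, Gaussian+Poisson noise, perfect registration. Parameter
recovery on them validates the *analysis logic* (geometry, statistics,
thresholds, fits) and the internal consistency of the forward model; it
does not validate the physical fidelity of any particular instrument, nor
performance under artifacts the model omits (glare, reflections, filter
leakage, autofocus breathing, demosaicing correlations).
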