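"""Forward model of an LED-excitation fluorescence imaging box.

Renders RGB frames in detector counts from physically parameterized scene
descriptions (well plates, gels, resolution/color/distortion targets,
minerals, growing specimens) under models of the LED sources, ideal step
emission filters, fluorophores, and the camera (black level, gain, read and
shot noise, clipping).

The pixel model is

    counts = clip(black_level + gain * signal + read_noise, 0, 2**bits - 1)

with, for a fluorophore at concentration ``c`` (molar),

    signal = k * c * f_sat(c) * excitation(drive) * emission_to_channel
             * exposure_ms * illumination_field

where ``f_sat(c) = (1 - 10**(-eps_l*c)) / (eps_l*c*ln 10)`` is an
inner-filter-style saturation factor normalized so ``f_sat -> 1`` as
``c -> 0``, and ``emission_to_channel`` distributes the emission lines that
pass the filter over the R, G, B channels by the camera's spectral response.
Shot noise, when enabled, draws ``signal`` from a Poisson law before the gain
is applied.  Every stochastic operation takes an explicit seed; sweeps derive
per-frame seeds as ``seed + index``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.optimize import root
from scipy.stats import norm

from .calibration import UsafElement, UsafRoi
from .core import AcquisitionSetting, ImageFrame, ImageStack, Region
from .platequant import PlateLayout

__all__ = [
    "CameraModel",
    "LedChannel",
    "LedModel",
    "FluorophoreModel",
    "PlateScene",
    "GelLane",
    "GelScene",
    "TargetScene",
    "MineralRegion",
    "MineralScene",
    "SpecimenScene",
    "render",
    "render_sweep",
    "render_series",
    "dark_stack",
    "radial_vignetting",
    "clipped_normal_moments",
    "clipped_normal_params",
    "presets",
]

LN10 = math.log(10.0)


# --------------------------------------------------------------------------
# instrument models
# --------------------------------------------------------------------------

def _default_channel_sensitivity(wavelength_nm: float) -> np.ndarray:
    """Relative RGB quantum efficiency of a typical color camera.

    Gaussian pass bands centered at 600 (R), 540 (G) and 465 (B) nm.
    """
    centers = np.array([600.0, 540.0, 465.0])
    widths = np.array([60.0, 50.0, 45.0])
    return np.exp(-0.5 * ((wavelength_nm - centers) / widths) ** 2)


@dataclass
class CameraModel:
    """Detector model: offset, gain, noise and clipping.

    ``black_level`` is the underlying per-channel offset in counts; it may be
    negative (the observable dark mean is then set by zero-clipping of the
    read noise).  ``gain`` converts photon-equivalent signal units to counts.
    """

    bit_depth: int = 8
    black_level: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))
    read_noise_sd: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))
    gain: float = 1.0
    shot_noise: bool = False
    channel_sensitivity: Callable[[float], np.ndarray] = _default_channel_sensitivity

    def __post_init__(self) -> None:
        self.black_level = np.broadcast_to(
            np.asarray(self.black_level, dtype=float), (3,)
        ).copy()
        self.read_noise_sd = np.broadcast_to(
            np.asarray(self.read_noise_sd, dtype=float), (3,)
        ).copy()
        if np.any(self.read_noise_sd < 0):
            raise ValueError("read noise sd must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")

    @property
    def saturation(self) -> float:
        return float(2**self.bit_depth - 1)

    @property
    def has_noise(self) -> bool:
        return self.shot_noise or bool(np.any(self.read_noise_sd > 0))


@dataclass
class LedChannel:
    peak_nm: float
    power_vs_drive: Callable[[float], float]
    irradiance_vs_distance: Callable[[float], float]

    def __post_init__(self) -> None:
        if abs(self.power_vs_drive(0.0)) > 1e-12:
            raise ValueError("power_vs_drive(0) must be 0")
        grid = np.linspace(0, 1, 21)
        vals = [self.power_vs_drive(float(g)) for g in grid]
        if np.any(np.diff(vals) < -1e-12):
            raise ValueError("power_vs_drive must be monotone nondecreasing")


def _linear_power(drive: float) -> float:
    return drive


def _inverse_square(distance_cm: float) -> float:
    return 1.0 / max(distance_cm, 0.5) ** 2


@dataclass
class LedModel:
    """The excitation sources: one entry per addressable LED channel."""

    channels: dict[str, LedChannel] = dc_field(default_factory=dict)

    @classmethod
    def default(cls) -> "LedModel":
        mk = lambda peak: LedChannel(peak, _linear_power, _inverse_square)
        return cls({"blue_460": mk(460.0), "green_520": mk(520.0), "red_630": mk(630.0)})

    def relative_power(self, channel: str, drive: float) -> float:
        if channel == "off":
            return 0.0
        if channel in self.channels:
            return float(self.channels[channel].power_vs_drive(drive))
        # externally driven sources (e.g. UV lamps under manual control)
        return 1.0


def filter_transmission(setting: AcquisitionSetting, wavelength_nm: float) -> float:
    """Ideal step transmission of the configured emission filter (0 or 1)."""
    if setting.filter_cuton_nm is None:
        return 1.0
    if setting.filter_kind == "longpass":
        return 1.0 if wavelength_nm >= setting.filter_cuton_nm else 0.0
    hw = setting.filter_halfwidth_nm or 0.0
    return 1.0 if abs(wavelength_nm - setting.filter_cuton_nm) <= hw else 0.0


@dataclass
class FluorophoreModel:
    """A fluorescent emitter: excitation efficiencies, discrete emission lines,
    a brightness constant and an inner-filter saturation parameter.

    ``brightness_k`` has units counts / M / ms (at unit drive and gain 1);
    ``eps_l`` is the molar-absorptivity x path-length product (1/M) that sets
    where the high-concentration roll-off begins.
    """

    excitation: dict[str, float]
    emission: list[tuple[float, float]]
    brightness_k: float
    eps_l: float = 0.0

    def __post_init__(self) -> None:
        w = np.array([wt for _, wt in self.emission], dtype=float)
        if np.any(w < 0) or not math.isclose(w.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("emission weights must be >= 0 and sum to 1")
        if self.brightness_k <= 0:
            raise ValueError("brightness constant must be > 0")
        if self.eps_l < 0:
            raise ValueError("eps_l must be >= 0")

    def f_sat(self, c) -> np.ndarray:
        """Saturation factor ``(1 - 10**(-eps_l*c)) / (eps_l*c*ln10)``.

        Strictly decreasing in ``c`` and -> 1 as ``c`` -> 0 (series expansion
        used below u = 1e-6 for numerical stability).
        """
        c = np.asarray(c, dtype=float)
        u = self.eps_l * c * LN10
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(u > 1e-6, -np.expm1(-u) / np.where(u > 0, u, 1.0),
                         1.0 - u / 2.0 + u**2 / 6.0)
        return f if f.ndim else float(f)

    def emission_rgb(self, setting: AcquisitionSetting, camera: CameraModel) -> np.ndarray:
        """Per-channel response to the filtered emission spectrum."""
        out = np.zeros(3)
        for lam, wt in self.emission:
            out += wt * filter_transmission(setting, lam) * camera.channel_sensitivity(lam)
        return out

    def well_rate(
        self, c, setting: AcquisitionSetting, camera: CameraModel, led: LedModel
    ) -> np.ndarray:
        """Expected signal rate (per ms, per channel) for concentration ``c``."""
        exc = self.excitation.get(setting.led_channel, 0.0)
        exc *= led.relative_power(setting.led_channel, setting.drive_level)
        rgb = self.emission_rgb(setting, camera)
        c = np.asarray(c, dtype=float)
        scalar = self.brightness_k * c * self.f_sat(c) * exc
        return np.multiply.outer(scalar, rgb)


def radial_vignetting(shape: tuple[int, int], amplitude: float) -> np.ndarray:
    """Illumination field ``1 - amplitude * (r / r_corner)**2`` about the center."""
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W]
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    r2 = (rr - cy) ** 2 + (cc - cx) ** 2
    return 1.0 - amplitude * r2 / r2.max()


# --------------------------------------------------------------------------
# scenes
# --------------------------------------------------------------------------

@dataclass
class PlateScene:
    """A multiwell plate with a fluorophore solution in each well."""

    layout: PlateLayout
    concentrations: dict[str, float]
    fluorophore: FluorophoreModel
    vignetting_amplitude: float = 0.0
    illumination_field: np.ndarray | None = None
    shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError("concentrations must be >= 0")

    def image_shape(self) -> tuple[int, int]:
        return self.shape if self.shape is not None else self.layout.image_shape()

    def field(self) -> np.ndarray:
        if self.illumination_field is not None:
            return self.illumination_field
        return radial_vignetting(self.image_shape(), self.vignetting_amplitude)

    def expected_rgb_rate(
        self, setting: AcquisitionSetting, camera: CameraModel, led: LedModel
    ) -> np.ndarray:
        shape = self.image_shape()
        out = np.zeros(shape + (3,))
        centers = self.layout.centers()
        radius = self.layout.well_radius_px
        for r in range(self.layout.n_rows):
            for c in range(self.layout.n_cols):
                label = self.layout.label(r, c)
                conc = self.concentrations.get(label, 0.0)
                if conc <= 0:
                    continue
                rate = self.fluorophore.well_rate(conc, setting, camera, led)
                reg = Region.disk(label, tuple(centers[r, c]), radius).clipped_to(shape)
                r0, c0, r1, c1 = reg.box
                out[r0:r1, c0:c1][reg.mask] = rate
        return out * self.field()[..., None]


@dataclass
class GelLane:
    load_amount: float
    band_sizes_bp: Sequence[float]


@dataclass
class GelScene:
    """An electrophoresis gel: Gaussian bands on a semilog migration model.

    Band center (px from the well row) for a fragment of ``s`` bp is
    ``migration_a - migration_b * log10(s)``; smaller fragments travel
    farther.  Band amplitude scales linearly with the lane load.
    """

    lanes: list[GelLane]
    migration_a: float = 625.0
    migration_b: float = 150.0
    band_sigma_px: float = 3.0
    lane_width_px: int = 40
    lane_pitch_px: int = 80
    well_row_px: int = 20
    amplitude_per_load: float = 1.0  # signal rate per ms per unit load per band
    fluorophore: FluorophoreModel | None = None
    shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.migration_b <= 0:
            raise ValueError("migration_b must be > 0")

    def band_center(self, size_bp: float) -> float:
        return self.well_row_px + self.migration_a - self.migration_b * math.log10(size_bp)

    def image_shape(self) -> tuple[int, int]:
        if self.shape is not None:
            return self.shape
        deepest = max(self.band_center(min(l.band_sizes_bp)) for l in self.lanes)
        h = int(deepest + 8 * self.band_sigma_px + 20)
        w = self.lane_pitch_px * len(self.lanes)
        return h, w

    def lane_box(self, i: int) -> tuple[int, int, int, int]:
        """Half-open (row0, col0, row1, col1) box covering lane ``i``."""
        h, _ = self.image_shape()
        c0 = self.lane_pitch_px * i + (self.lane_pitch_px - self.lane_width_px) // 2
        return (self.well_row_px, c0, h, c0 + self.lane_width_px)

    def expected_rgb_rate(
        self, setting: AcquisitionSetting, camera: CameraModel, led: LedModel
    ) -> np.ndarray:
        fluor = self.fluorophore or presets.sybr_safe()
        exc = fluor.excitation.get(setting.led_channel, 0.0)
        exc *= led.relative_power(setting.led_channel, setting.drive_level)
        rgb = fluor.emission_rgb(setting, camera) * exc
        shape = self.image_shape()
        out = np.zeros(shape + (3,))
        rows = np.arange(shape[0], dtype=float)
        for i, lane in enumerate(self.lanes):
            profile = np.zeros(shape[0])
            for size in lane.band_sizes_bp:
                yb = self.band_center(size)
                profile += np.exp(-0.5 * ((rows - yb) / self.band_sigma_px) ** 2)
            profile *= self.amplitude_per_load * lane.load_amount
            _, c0, _, c1 = self.lane_box(i)
            out[:, c0:c1, :] = profile[:, None, None] * rgb[None, None, :]
        return out


#: Classic 24-patch color-checker sRGB values (8-bit), row-major.
CLASSIC_CHECKER_SRGB = np.array(
    [
        [115, 82, 68], [194, 150, 130], [98, 122, 157], [87, 108, 67],
        [133, 128, 177], [103, 189, 170], [214, 126, 44], [80, 91, 166],
        [193, 90, 99], [94, 60, 108], [157, 188, 64], [224, 163, 46],
        [56, 61, 150], [70, 148, 73], [175, 54, 60], [231, 199, 31],
        [187, 86, 149], [8, 133, 161], [243, 243, 242], [200, 200, 200],
        [160, 160, 160], [122, 122, 121], [85, 85, 85], [52, 52, 52],
    ],
    dtype=float,
)


def _coverage(n: int, intervals: list[tuple[float, float]]) -> np.ndarray:
    """Fraction of each unit pixel [x-0.5, x+0.5) covered by the intervals."""
    x = np.arange(n, dtype=float)
    cov = np.zeros(n)
    for lo, hi in intervals:
        cov += np.clip(np.minimum(hi, x + 0.5) - np.maximum(lo, x - 0.5), 0.0, 1.0)
    return np.clip(cov, 0.0, 1.0)


@dataclass
class TargetScene:
    """A calibration target: 1951 USAF chart, color checker, or line grid."""

    kind: str = "usaf1951"
    scale_px_per_mm: float = 100.0
    blur_sigma_um: float = 0.0
    k1: float = 0.0  # injected radial distortion, px^-2
    peak_rate: float = 2.0  # counts per ms at full reflectance
    usaf_groups: Sequence[int] = (0, 1, 2, 3)
    grid_spacing_mm: float = 0.5
    grid_line_width_mm: float = 0.03
    grid_n_lines: int = 19
    checker_patch_px: int = 40
    pad_mm: float = 0.25

    _usaf_rois: list[UsafRoi] = dc_field(default_factory=list, init=False, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("usaf1951", "color_checker", "distortion_grid"):
            raise ValueError(f"unknown target kind {self.kind!r}")
        if self.scale_px_per_mm <= 0:
            raise ValueError("scale must be > 0")

    # -- pattern builders ---------------------------------------------------

    def _usaf_pattern(self) -> np.ndarray:
        scale = self.scale_px_per_mm
        pad = self.pad_mm * scale
        self._usaf_rois = []
        columns = []
        heights = []
        for g in self.usaf_groups:
            col_w = 5 * scale / (2.0 ** (g + 1))
            col_h = sum(5 * scale / (2.0 ** (g + 1 + (e - 1) / 6.0)) for e in range(1, 7))
            columns.append(col_w)
            heights.append(col_h + 7 * pad)
        H = int(math.ceil(max(heights)))
        W = int(math.ceil(sum(columns) + pad * (len(columns) + 1)))
        pattern = np.zeros((H, W))
        x_off = pad
        for g in self.usaf_groups:
            y_off = pad
            for e in range(1, 7):
                elem = UsafElement(group=g, element=e)
                bar_w = scale / (2.0 * elem.frequency_lp_mm)
                bar_h = 5 * bar_w
                intervals = [(x_off + k * 2 * bar_w, x_off + (k * 2 + 1) * bar_w)
                             for k in range(3)]
                cov_x = _coverage(W, intervals)
                cov_y = _coverage(H, [(y_off, y_off + bar_h)])
                pattern += np.outer(cov_y, cov_x)
                y_mid = y_off + bar_h / 2.0
                self._usaf_rois.append(
                    UsafRoi(
                        element=elem,
                        profile_start=(y_mid, x_off + 0.5 * bar_w),
                        profile_end=(y_mid, x_off + 4.5 * bar_w),
                    )
                )
                y_off += bar_h + pad
            x_off += 5 * scale / (2.0 ** (g + 1)) + pad
        return np.clip(pattern, 0.0, 1.0)[..., None] * np.ones(3)

    def _grid_pattern(self) -> np.ndarray:
        scale = self.scale_px_per_mm
        spacing = self.grid_spacing_mm * scale
        lw = self.grid_line_width_mm * scale
        n = self.grid_n_lines
        size = int(math.ceil(spacing * (n + 1)))
        lines = [(spacing * (i + 1) - lw / 2, spacing * (i + 1) + lw / 2) for i in range(n)]
        cov = _coverage(size, lines)
        dark = np.maximum.outer(cov, cov)  # union of horizontal + vertical lines
        pattern = 0.9 - 0.8 * dark
        return pattern[..., None] * np.ones(3)

    def _checker_pattern(self) -> np.ndarray:
        p = self.checker_patch_px
        gap = max(p // 8, 2)
        H = 4 * p + 5 * gap
        W = 6 * p + 7 * gap
        pattern = np.zeros((H, W, 3))
        for i in range(4):
            for j in range(6):
                r0 = gap + i * (p + gap)
                c0 = gap + j * (p + gap)
                pattern[r0 : r0 + p, c0 : c0 + p] = CLASSIC_CHECKER_SRGB[i * 6 + j] / 255.0
        return pattern

    def pattern(self) -> np.ndarray:
        if self.kind == "usaf1951":
            return self._usaf_pattern()
        if self.kind == "distortion_grid":
            return self._grid_pattern()
        return self._checker_pattern()

    def usaf_rois(self) -> list[UsafRoi]:
        """Profile locations for each rendered element (undistorted layout)."""
        if self.kind != "usaf1951":
            raise ValueError("rois only defined for the usaf1951 target")
        if not self._usaf_rois:
            self._usaf_pattern()
        return list(self._usaf_rois)

    def checker_patch_regions(self) -> list[Region]:
        if self.kind != "color_checker":
            raise ValueError("patch regions only defined for the color checker")
        p = self.checker_patch_px
        gap = max(p // 8, 2)
        regions = []
        m = p // 5  # stay inside the patch
        for i in range(4):
            for j in range(6):
                r0 = gap + i * (p + gap)
                c0 = gap + j * (p + gap)
                regions.append(
                    Region(f"patch{i * 6 + j + 1}", (r0 + m, c0 + m, r0 + p - m, c0 + p - m))
                )
        return regions

    def _distort(self, pattern: np.ndarray) -> np.ndarray:
        """Warp by the radial model r' = r (1 + k1 r^2) about the image center."""
        if self.k1 == 0.0:
            return pattern
        H, W = pattern.shape[:2]
        cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
        rr, cc = np.mgrid[0:H, 0:W].astype(float)
        dy, dx = rr - cy, cc - cx
        rp = np.hypot(dy, dx)
        r = rp.copy()
        for _ in range(4):  # fixed-point inversion of r' = r(1 + k1 r^2)
            r = rp / (1.0 + self.k1 * r**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(rp > 0, r / rp, 1.0)
        coords = np.array([cy + dy * f, cx + dx * f])
        out = np.empty_like(pattern)
        for ch in range(pattern.shape[2]):
            out[..., ch] = map_coordinates(pattern[..., ch], coords, order=1, mode="nearest")
        return out

    def expected_rgb_rate(
        self, setting: AcquisitionSetting, camera: CameraModel, led: LedModel
    ) -> np.ndarray:
        # reflective target under full-spectrum illumination: the LED spectral
        # model is bypassed and brightness scales with peak_rate alone
        pattern = self._distort(self.pattern())
        sigma_px = self.blur_sigma_um * self.scale_px_per_mm / 1000.0
        if sigma_px > 0:
            pattern = gaussian_filter(pattern, sigma=(sigma_px, sigma_px, 0))
        return pattern * self.peak_rate


@dataclass
class MineralRegion:
    label: str
    box: tuple[int, int, int, int]
    emission: list[tuple[float, float]]  # (wavelength nm, weight), weights sum to 1
    brightness_rate: float  # signal per ms under the UV source


@dataclass
class MineralScene:
    """Fluorescent mineral specimens with distinct line-emission spectra."""

    regions: list[MineralRegion]
    shape: tuple[int, int] = (240, 360)

    def expected_rgb_rate(
        self, setting: AcquisitionSetting, camera: CameraModel, led: LedModel
    ) -> np.ndarray:
        exc = led.relative_power(setting.led_channel, setting.drive_level)
        out = np.zeros(self.shape + (3,))
        for reg in self.regions:
            rgb = np.zeros(3)
            for lam, wt in reg.emission:
                rgb += wt * filter_transmission(setting, lam) * camera.channel_sensitivity(lam)
            r0, c0, r1, c1 = reg.box
            out[r0:r1, c0:c1] = reg.brightness_rate * exc * rgb
        return out


@dataclass
class SpecimenScene:
    """A bright elliptical specimen on a dark background (one time point)."""

    semi_axes_px: tuple[float, float]  # (row semi-axis, col semi-axis)
    center: tuple[float, float] | None = None
    body_rate: float = 1.2
    background_rate: float = 0.05
    body_rgb: tuple[float, float, float] = (0.35, 0.85, 0.30)
    shape: tuple[int, int] = (400, 400)

    def expected_rgb_rate(
        self, setting: AcquisitionSetting, camera: CameraModel, led: LedModel
    ) -> np.ndarray:
        a, b = self.semi_axes_px
        cy, cx = self.center or ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)
        rr, cc = np.mgrid[0 : self.shape[0], 0 : self.shape[1]]
        inside = ((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1.0
        rgb = np.asarray(self.body_rgb, dtype=float)
        out = np.full(self.shape + (3,), self.background_rate)
        out[inside] = self.body_rate * rgb
        return out

    def area_px2(self) -> float:
        return math.pi * self.semi_axes_px[0] * self.semi_axes_px[1]


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def render(
    scene,
    setting: AcquisitionSetting,
    camera: CameraModel,
    led: LedModel | None = None,
    seed: int = 0,
) -> ImageFrame:
    """Render one frame.  Deterministic given the seed; exactly reproducible."""
    led = led if led is not None else LedModel.default()
    signal = scene.expected_rgb_rate(setting, camera, led) * setting.exposure_ms
    rng = np.random.default_rng(seed)
    if camera.shot_noise:
        signal = rng.poisson(np.maximum(signal, 0.0)).astype(float)
    counts = camera.black_level + camera.gain * signal
    if np.any(camera.read_noise_sd > 0):
        counts = counts + rng.normal(0.0, camera.read_noise_sd, counts.shape)
    counts = np.clip(counts, 0.0, camera.saturation)
    return ImageFrame(pixels=counts, bit_depth=camera.bit_depth, setting=setting)


def render_sweep(
    scene,
    settings: Sequence[AcquisitionSetting],
    camera: CameraModel,
    led: LedModel | None = None,
    seed: int = 0,
) -> ImageStack:
    """One frame per acquisition setting; frame ``i`` uses seed ``seed + i``."""
    if not settings:
        raise ValueError("need at least one setting")
    frames = [render(scene, s, camera, led, seed=seed + i) for i, s in enumerate(settings)]
    return ImageStack(frames=frames)


def render_series(
    scenes: Sequence,
    setting: AcquisitionSetting,
    camera: CameraModel,
    led: LedModel | None = None,
    seed: int = 0,
    times: Sequence[float] | None = None,
) -> ImageStack:
    """Render a time-lapse: one frame per scene under a fixed setting."""
    frames = [render(sc, setting, camera, led, seed=seed + i) for i, sc in enumerate(scenes)]
    return ImageStack(frames=frames, acquisition_times=times)


def dark_stack(
    camera: CameraModel, n_frames: int, height: int, width: int, seed: int = 0
) -> ImageStack:
    """Dark frames: black level plus Gaussian read noise, clipped to range."""
    if n_frames < 1:
        raise ValueError("need at least one frame")
    setting = AcquisitionSetting(exposure_ms=1.0, led_channel="off", drive_level=0.0)
    frames = []
    for i in range(n_frames):
        rng = np.random.default_rng(seed + i)
        px = np.broadcast_to(camera.black_level, (height, width, 3)).copy()
        if np.any(camera.read_noise_sd > 0):
            px = px + rng.normal(0.0, camera.read_noise_sd, px.shape)
        px = np.clip(px, 0.0, camera.saturation)
        frames.append(ImageFrame(pixels=px, bit_depth=camera.bit_depth, setting=setting))
    return ImageStack(frames=frames)


# --------------------------------------------------------------------------
# zero-clipped Gaussian moments (dark-frame statistics)
# --------------------------------------------------------------------------

def clipped_normal_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Mean and std of ``max(0, N(mu, sigma))`` in closed form."""
    if sigma <= 0:
        m = max(mu, 0.0)
        return m, 0.0
    a = mu / sigma
    phi, Phi = norm.pdf(a), norm.cdf(a)
    m1 = mu * Phi + sigma * phi
    m2 = (mu**2 + sigma**2) * Phi + mu * sigma * phi
    var = max(m2 - m1**2, 0.0)
    return float(m1), float(math.sqrt(var))


def clipped_normal_params(mean: float, sd: float) -> tuple[float, float]:
    """Invert the zero-clipped normal moment equations.

    Finds the underlying ``(mu, sigma)`` whose clipped distribution has the
    observed ``mean`` and ``sd`` — e.g. to moment-match synthetic dark frames
    to measured dark statistics.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError("observed mean and sd must be positive")

    def eqs(p):
        m, s = clipped_normal_moments(p[0], abs(p[1]))
        return [m - mean, s - sd]

    sol = root(eqs, x0=[mean, sd], method="hybr")
    if not sol.success:
        raise RuntimeError(f"moment inversion failed: {sol.message}")
    mu, sigma = float(sol.x[0]), float(abs(sol.x[1]))
    return mu, sigma


# --------------------------------------------------------------------------
# presets emulating the reference experiments
# --------------------------------------------------------------------------

class presets:
    """Scene/camera presets mirroring the characterization experiments."""

    #: dark-frame statistics of the reference color camera (counts, 8-bit)
    DARK_MEANS = (0.50, 0.36, 0.57)
    DARK_STDS = (0.84, 0.68, 0.87)

    #: 1 kb DNA ladder fragment sizes (bp)
    LADDER_1KB = (250, 500, 750, 1000, 1500, 2000, 2500, 3000,
                  3500, 4000, 5000, 6000, 8000, 10000)

    #: long-pass filter cut-ons of the stock filter set (nm)
    LONGPASS_CUTONS = (435, 455, 495, 515, 530, 550, 570, 590, 610, 630, 645, 665, 695)

    @staticmethod
    def ideal_camera(bit_depth: int = 8) -> CameraModel:
        return CameraModel(bit_depth=bit_depth)

    @staticmethod
    def dark_matched_camera() -> CameraModel:
        """Underlying offsets/noise moment-matched to the reference dark stats."""
        mus, sigmas = [], []
        for m, s in zip(presets.DARK_MEANS, presets.DARK_STDS):
            mu, sigma = clipped_normal_params(m, s)
            mus.append(mu)
            sigmas.append(sigma)
        return CameraModel(black_level=np.array(mus), read_noise_sd=np.array(sigmas))

    @staticmethod
    def fitc(brightness_k: float = 1e10) -> FluorophoreModel:
        """FITC-like dye: blue excitation, green emission near 520/545 nm."""
        return FluorophoreModel(
            excitation={"blue_460": 1.0, "green_520": 0.15},
            emission=[(520.0, 0.6), (545.0, 0.4)],
            brightness_k=brightness_k,
            eps_l=3.75e4,  # ~ molar absorptivity x cm-scale path
        )

    @staticmethod
    def sybr_safe() -> FluorophoreModel:
        """SYBR-type gel stain: blue excitation, emission peak with the long
        tail that passes a 530 nm long-pass filter."""
        return FluorophoreModel(
            excitation={"blue_460": 1.0},
            emission=[(535.0, 0.6), (570.0, 0.4)],
            brightness_k=1.0,
            eps_l=0.0,
        )

    @staticmethod
    def fitc_setting(exposure_ms: float) -> AcquisitionSetting:
        """Blue excitation through the 542 +/- 25 nm bandpass filter."""
        return AcquisitionSetting(
            exposure_ms=exposure_ms,
            led_channel="blue_460",
            drive_level=1.0,
            filter_cuton_nm=542.0,
            filter_kind="bandpass",
            filter_halfwidth_nm=25.0,
        )

    @staticmethod
    def fitc_dilution(
        read_noise_sd: float = 0.5,
        shot_noise: bool = True,
        brightness_k: float = 1e10,
    ):
        """The serial-dilution sensitivity experiment.

        Ten decades of FITC (1e-3 .. 1e-12 M) in columns 1-10, triplicate
        rows A-C, blank wells (concentration 0) in row D.  Returns
        ``(scene, plate_map, camera, settings)`` with the exposure sweep
        {1, 10, 100, 1000, 2000, 10000} ms.
        """
        layout = PlateLayout()
        concs = [10.0 ** (-3 - i) for i in range(10)]
        plate_map: dict[str, float] = {}
        for col, c in enumerate(concs):
            for row in "ABC":
                plate_map[f"{row}{col + 1}"] = c
            plate_map[f"D{col + 1}"] = 0.0
        scene = PlateScene(
            layout=layout,
            concentrations={k: v for k, v in plate_map.items() if v > 0},
            fluorophore=presets.fitc(brightness_k),
        )
        camera = CameraModel(
            read_noise_sd=np.full(3, read_noise_sd), shot_noise=shot_noise
        )
        settings = [presets.fitc_setting(t) for t in (1, 10, 100, 1000, 2000, 10000)]
        return scene, plate_map, camera, settings

    @staticmethod
    def flatness_plate(
        snr: float = 200.0,
        vignetting_amplitude: float = 0.02,
        target_counts: float = 180.0,
        exposure_ms: float = 10.0,
        disk_fraction: float = 0.8,
    ):
        """The uniform 10 uM FITC flatness plate.

        All 96 wells hold the same concentration; a radial vignetting field of
        the given amplitude is applied and the camera noise (shot + read) is
        sized so the per-well SNR — well-mean signal over the standard error
        of the disk mean — equals ``snr``.  Returns ``(scene, camera,
        setting)``.
        """
        layout = PlateLayout()
        c = 1e-5  # 10 uM
        setting = presets.fitc_setting(exposure_ms)
        fluor = presets.fitc(brightness_k=1.0)
        camera = CameraModel(shot_noise=True)
        led = LedModel.default()
        unit = fluor.well_rate(c, setting, camera, led) * exposure_ms  # per unit k
        from .core import GRAY_WEIGHTS

        unit_gray = float(unit @ GRAY_WEIGHTS)
        k = target_counts / unit_gray
        fluor = presets.fitc(brightness_k=k)
        per_channel = fluor.well_rate(c, setting, camera, led) * exposure_ms
        # pixels in the measurement disk
        n_pix = math.pi * (disk_fraction * layout.well_radius_px) ** 2
        var_needed = n_pix * (target_counts / snr) ** 2  # per-pixel gray variance
        var_shot = float(np.sum(GRAY_WEIGHTS**2 * per_channel))
        var_read = max(var_needed - var_shot, 0.0)
        read_sd = math.sqrt(var_read / float(np.sum(GRAY_WEIGHTS**2)))
        camera = CameraModel(read_noise_sd=np.full(3, read_sd), shot_noise=True)
        concentrations = {
            layout.label(r, cidx): c
            for r in range(layout.n_rows)
            for cidx in range(layout.n_cols)
        }
        scene = PlateScene(
            layout=layout,
            concentrations=concentrations,
            fluorophore=fluor,
            vignetting_amplitude=vignetting_amplitude,
        )
        return scene, camera, setting

    @staticmethod
    def usaf_target(
        scale_px_per_mm: float = 100.0, blur_sigma_um: float = 30.0
    ) -> TargetScene:
        return TargetScene(
            kind="usaf1951",
            scale_px_per_mm=scale_px_per_mm,
            blur_sigma_um=blur_sigma_um,
        )

    @staticmethod
    def distortion_grid(k1: float = 0.0) -> TargetScene:
        return TargetScene(kind="distortion_grid", k1=k1)

    @staticmethod
    def color_checker() -> TargetScene:
        return TargetScene(kind="color_checker", peak_rate=2.55)

    @staticmethod
    def gel_1kb() -> GelScene:
        """Four-lane 1 kb ladder gel: 10, 10, 20, 20 units loaded."""
        lanes = [GelLane(load, presets.LADDER_1KB) for load in (10.0, 10.0, 20.0, 20.0)]
        return GelScene(lanes=lanes, amplitude_per_load=0.02)

    @staticmethod
    def minerals() -> MineralScene:
        """Nine fluorescent minerals with distinct line emission spectra."""
        specs = [
            ("hackmanite", [(620.0, 1.0)], 1.2),
            ("scapolite", [(590.0, 0.7), (620.0, 0.3)], 1.0),
            ("calcite_mt", [(610.0, 1.0)], 1.4),
            ("selenite", [(480.0, 1.0)], 0.8),
            ("fluorite", [(450.0, 0.8), (530.0, 0.2)], 1.5),
            ("turritella", [(540.0, 1.0)], 0.6),
            ("tremolite", [(560.0, 0.5), (600.0, 0.5)], 1.1),
            ("calcite_mx", [(640.0, 1.0)], 1.3),
            ("quartzite", [(500.0, 0.6), (580.0, 0.4)], 0.9),
        ]
        regions = []
        for i, (label, emission, rate) in enumerate(specs):
            r, c = divmod(i, 3)
            box = (20 + r * 75, 30 + c * 110, 70 + r * 75, 110 + c * 110)
            regions.append(MineralRegion(label, box, emission, rate))
        return MineralScene(regions=regions)

    @staticmethod
    def hornworm(
        n_days: int = 10, growth_rate_per_day: float = 0.3
    ) -> tuple[list[SpecimenScene], list[float]]:
        """A specimen growing exponentially in area over ``n_days`` days."""
        scenes, times = [], []
        for d in range(n_days):
            f = math.exp(growth_rate_per_day * d / 2.0)  # per-axis factor
            scenes.append(
                SpecimenScene(semi_axes_px=(14.0 * f, 34.0 * f), body_rate=1.2)
            )
            times.append(float(d))
        return scenes, times
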