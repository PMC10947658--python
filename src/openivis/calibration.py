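"""Camera and system characterization.

Covers the standard bench checks run on a fluorescence imaging box: dark-frame
black level, color-checker accuracy (CIE76 ΔE), radial lens distortion from a
grid chart, LED power linearity versus drive level, and optical resolution
from a 1951 USAF three-bar target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, minimum_filter1d
from skimage.color import deltaE_cie76, rgb2lab
from skimage.feature import peak_local_max

from .core import ImageFrame, ImageStack, line_profile, stack_mean_std

__all__ = [
    "UsafElement",
    "UsafRoi",
    "BlackLevelResult",
    "LinearityFit",
    "DistortionResult",
    "black_level",
    "color_accuracy",
    "distortion_check",
    "led_linearity",
    "usaf_resolution",
    "lp_per_mm_to_um",
]


@dataclass(frozen=True)
class UsafElement:
    """One three-bar element of a 1951 USAF target."""

    group: int
    element: int

    def __post_init__(self) -> None:
        if not 1 <= self.element <= 6:
            raise ValueError("element must be 1-6")

    @property
    def frequency_lp_mm(self) -> float:
        """Spatial frequency ``2**(group + (element-1)/6)`` in line pairs/mm."""
        return float(2.0 ** (self.group + (self.element - 1) / 6.0))


@dataclass(frozen=True)
class UsafRoi:
    """Where to read an element's bar profile in a rendered/registered image.

    The profile runs perpendicular to the bars from the center of the first
    bar to the center of the third, so it crosses exactly two gaps.
    """

    element: UsafElement
    profile_start: tuple[float, float]
    profile_end: tuple[float, float]


@dataclass
class BlackLevelResult:
    means: np.ndarray
    stds: np.ndarray
    calibration_needed: bool
    threshold: float


def black_level(dark: ImageStack, threshold: float = 1.0) -> BlackLevelResult:
    """Per-channel dark-frame mean/std and a pass/fail offset check.

    A channel mean above ``threshold`` counts flags that black-level
    calibration is needed; the reference camera sits near half a count per
    channel and needs none.
    """
    means, stds = stack_mean_std(dark)
    return BlackLevelResult(
        means=means,
        stds=stds,
        calibration_needed=bool(np.any(means > threshold)),
        threshold=threshold,
    )


def color_accuracy(
    measured_patches: np.ndarray, reference_patches: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """CIE76 ΔE between measured and reference sRGB patch values.

    Inputs are ``N x 3`` arrays of 8-bit sRGB values (0-255); conversion to
    CIELAB uses the sRGB transfer curve under D65.  Returns the per-patch ΔE
    vector plus its mean and max.
    """
    m = np.asarray(measured_patches, dtype=float)
    r = np.asarray(reference_patches, dtype=float)
    if m.shape != r.shape:
        raise ValueError(f"patch list shapes differ: {m.shape} vs {r.shape}")
    if m.ndim != 2 or m.shape[1] != 3:
        raise ValueError("patches must be N x 3 RGB")
    lab_m = rgb2lab(m[None, :, :] / 255.0)[0]
    lab_r = rgb2lab(r[None, :, :] / 255.0)[0]
    de = deltaE_cie76(lab_m, lab_r)
    return de, float(de.mean()), float(de.max())


@dataclass
class DistortionResult:
    k1: float
    classification: str  # none | barrel | pincushion
    n_crossings: int
    spacing_px: float


def _crossing_points(img: np.ndarray, spacing: float) -> np.ndarray:
    """Detect grid-line crossings: points dark along both axes."""
    inv = img.max() - img
    inv = gaussian_filter(inv, 1.0)
    w = max(int(spacing * 0.4) | 1, 3)
    horiz = minimum_filter1d(inv, size=w, axis=1)
    vert = minimum_filter1d(inv, size=w, axis=0)
    resp = horiz + vert
    pts = peak_local_max(
        resp,
        min_distance=max(int(spacing * 0.4), 3),
        threshold_abs=0.5 * resp.max(),
        exclude_border=int(spacing * 0.25),
    )
    return pts.astype(float)


def _estimate_spacing(img: np.ndarray) -> float:
    """Dominant line spacing from the autocorrelation of the grid image."""
    g = img - img.mean()
    f = np.fft.rfft2(g)
    acf = np.fft.irfft2(np.abs(f) ** 2, s=g.shape)
    from scipy.signal import find_peaks

    spacings = []
    for prof in (acf[:, 0][: img.shape[0] // 2], acf[0, :][: img.shape[1] // 2]):
        peaks, _ = find_peaks(prof, prominence=0.1 * prof.max())
        if len(peaks):
            spacings.append(float(peaks[0]))  # fundamental period, not a harmonic
    if not spacings:
        raise ValueError("no grid periodicity found")
    return float(np.mean(spacings))


def distortion_check(
    grid_image: ImageFrame,
    spacing_hint: float | None = None,
    tol: float = 1e-8,
    channel: str = "gray",
) -> DistortionResult:
    """Estimate the first radial distortion coefficient from a grid chart.

    Grid-line crossings are detected, indexed against an ideal lattice fitted
    to the near-center crossings (where distortion is negligible), and the
    radial model ``r' = r (1 + k1 r^2)`` about the image center is fitted by
    least squares.  ``|k1| < tol`` (default 1e-8 px^-2) classifies as 'none';
    negative k1 is barrel, positive is pincushion.
    """
    img = grid_image.channel(channel)
    spacing = spacing_hint if spacing_hint is not None else _estimate_spacing(img)
    pts = _crossing_points(img, spacing)
    if len(pts) < 9:
        raise ValueError(f"found only {len(pts)} grid crossings; need at least 9")
    center = np.array([(img.shape[0] - 1) / 2.0, (img.shape[1] - 1) / 2.0])
    rel = pts - center
    # index each crossing on the lattice, anchored at the crossing nearest center
    anchor = rel[np.argmin(np.hypot(rel[:, 0], rel[:, 1]))]
    idx = np.round((rel - anchor) / spacing)
    # refine lattice origin/spacing on near-center points where distortion ~ 0
    r_meas = np.hypot(rel[:, 0], rel[:, 1])
    near = r_meas < 0.35 * r_meas.max()
    if near.sum() < 4:
        near = np.zeros(len(pts), dtype=bool)
        near[np.argsort(r_meas)[: max(4, len(pts) // 4)]] = True
    A = np.column_stack([np.ones(np.count_nonzero(near)), idx[near][:, 0]])
    oy, sy = np.linalg.lstsq(A, rel[near][:, 0], rcond=None)[0]
    A[:, 1] = idx[near][:, 1]
    ox, sx = np.linalg.lstsq(A, rel[near][:, 1], rcond=None)[0]
    ideal = np.column_stack([oy + sy * idx[:, 0], ox + sx * idx[:, 1]])
    r_ideal = np.hypot(ideal[:, 0], ideal[:, 1])
    ok = r_ideal > 1e-6
    k1 = float(np.sum(r_ideal[ok] ** 3 * (r_meas[ok] - r_ideal[ok])) / np.sum(r_ideal[ok] ** 6))
    if abs(k1) < tol:
        cls = "none"
    else:
        cls = "barrel" if k1 < 0 else "pincushion"
    return DistortionResult(k1=k1, classification=cls, n_crossings=len(pts),
                            spacing_px=float((abs(sy) + abs(sx)) / 2))


@dataclass
class LinearityFit:
    slope: float
    intercept: float
    r_squared: float
    residuals: np.ndarray
    worst_index: int


def led_linearity(drive_levels, powers) -> LinearityFit:
    """Ordinary least-squares fit of measured power versus LED drive level.

    Returns slope, intercept, R² and per-point residuals, highlighting the
    worst point (the kind of deviation seen around the 60-70% drive level on
    some LED channels).  Zero-variance powers yield slope 0 and R² reported
    as 0 with a warning.
    """
    d = np.asarray(drive_levels, dtype=float)
    p = np.asarray(powers, dtype=float)
    if d.size != p.size:
        raise ValueError("drive and power lists must match in length")
    if d.size < 3:
        raise ValueError("need at least 3 points")
    if np.unique(d).size != d.size:
        raise ValueError("drive levels must be distinct")
    if np.ptp(p) == 0:
        warnings.warn("constant power response: R^2 undefined, reported as 0")
        resid = np.zeros_like(p)
        return LinearityFit(0.0, float(p[0]), 0.0, resid, 0)
    slope, intercept = np.polyfit(d, p, 1)
    fitted = slope * d + intercept
    resid = p - fitted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((p - p.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return LinearityFit(float(slope), float(intercept), r2, resid, int(np.argmax(np.abs(resid))))


def usaf_resolution(
    image: ImageFrame,
    rois: list[UsafRoi],
    contrast_threshold: float = 0.1,
    channel: str = "gray",
) -> tuple[float, UsafElement, dict[tuple[int, int], float]]:
    """Finest resolvable USAF element by Michelson contrast.

    For each element (coarse to fine) the bar profile is sampled and its
    Michelson contrast ``(Imax - Imin) / (Imax + Imin)`` computed; scanning
    stops at the first element below ``contrast_threshold`` (contrast is
    required to degrade monotonically with frequency).  Returns the finest
    passing frequency (lp/mm), its element, and all measured contrasts.
    """
    if not rois:
        raise ValueError("no target elements supplied")
    ordered = sorted(rois, key=lambda r: r.element.frequency_lp_mm)
    contrasts: dict[tuple[int, int], float] = {}
    best: UsafElement | None = None
    for roi in ordered:
        prof = line_profile(image, roi.profile_start, roi.profile_end, channel=channel)
        hi, lo = float(prof.max()), float(prof.min())
        contrast = 0.0 if hi + lo == 0 else (hi - lo) / (hi + lo)
        contrasts[(roi.element.group, roi.element.element)] = contrast
        if contrast >= contrast_threshold:
            best = roi.element
        else:
            break
    if best is None:
        raise ValueError("below coarsest group: no element resolvable")
    return best.frequency_lp_mm, best, contrasts


def lp_per_mm_to_um(frequency_lp_mm: float) -> float:
    """Line width (μm) of a spatial frequency: one line is half a line pair.

    ``width = 500 / f``; e.g. 7 lp/mm corresponds to a ~70 μm line.
    """
    if frequency_lp_mm <= 0:
        raise ValueError("frequency must be positive")
    return 500.0 / frequency_lp_mm
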