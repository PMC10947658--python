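"""Shared image containers, acquisition metadata, and pixel statistics.

Images are held as float arrays of detector counts in ``H x W x 3`` (R, G, B)
layout; quantization to integer pixel values happens only when a frame is
written to disk.  Pixel coordinates are 0-based and row-major, boxes are
half-open, and pixel centers sit at integer coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "LED_CHANNELS",
    "AcquisitionSetting",
    "ImageFrame",
    "ImageStack",
    "Region",
    "GRAY_WEIGHTS",
    "to_gray",
    "stack_mean_std",
    "region_intensity",
    "line_profile",
]

#: Recognized LED excitation channels (peak wavelengths of the RGB LED module
#: are 460, 520 and 630 nm; ``external_uv`` covers externally driven sources).
LED_CHANNELS = ("blue_460", "green_520", "red_630", "external_uv", "off")

#: Rec. 601 luma weights used for RGB -> gray channel combination.
GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class AcquisitionSetting:
    """The acquisition knobs: exposure, LED drive and emission filter.

    Parameters
    ----------
    exposure_ms:
        Camera shutter time in milliseconds; must be positive.
    led_channel:
        One of :data:`LED_CHANNELS`.
    drive_level:
        Fractional LED power command in ``[0, 1]``.
    filter_cuton_nm:
        Cut-on wavelength of a long-pass emission filter (nm), or the center
        wavelength when ``filter_kind='bandpass'``.  ``None`` means no filter.
    filter_kind:
        ``'longpass'`` or ``'bandpass'``.
    filter_halfwidth_nm:
        Half-width of the pass band for a bandpass filter (nm).
    """

    exposure_ms: float = 100.0
    led_channel: str = "blue_460"
    drive_level: float = 1.0
    filter_cuton_nm: float | None = None
    filter_kind: str = "longpass"
    filter_halfwidth_nm: float | None = None

    def __post_init__(self) -> None:
        if self.exposure_ms <= 0:
            raise ValueError(f"exposure_ms must be > 0, got {self.exposure_ms}")
        if not 0.0 <= self.drive_level <= 1.0:
            raise ValueError(f"drive_level must be in [0, 1], got {self.drive_level}")
        if self.led_channel not in LED_CHANNELS:
            raise ValueError(
                f"unknown LED channel {self.led_channel!r}; expected one of {LED_CHANNELS}"
            )
        if self.filter_kind not in ("longpass", "bandpass"):
            raise ValueError(f"unknown filter kind {self.filter_kind!r}")
        if self.filter_kind == "bandpass" and self.filter_cuton_nm is not None:
            if not self.filter_halfwidth_nm or self.filter_halfwidth_nm <= 0:
                raise ValueError("bandpass filter needs a positive halfwidth")


@dataclass
class ImageFrame:
    """A demosaiced RGB image in detector counts plus its acquisition metadata."""

    pixels: np.ndarray
    bit_depth: int = 8
    setting: AcquisitionSetting = field(default_factory=AcquisitionSetting)
    pixel_pitch_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")
        if np.any(self.pixels < 0) or np.any(self.pixels > self.saturation):
            raise ValueError(
                f"counts must lie in [0, {self.saturation}] for bit depth {self.bit_depth}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    @property
    def saturation(self) -> float:
        return float(2**self.bit_depth - 1)

    def channel(self, name: str) -> np.ndarray:
        """Return one channel ('R', 'G', 'B') or the Rec. 601 'gray' combination."""
        if name == "gray":
            return to_gray(self)
        try:
            idx = "RGB".index(name)
        except ValueError:
            raise ValueError(f"unknown channel {name!r}; expected R, G, B or gray") from None
        return self.pixels[:, :, idx]

    def with_pixels(self, pixels: np.ndarray) -> "ImageFrame":
        return replace(self, pixels=pixels)


@dataclass
class ImageStack:
    """An ordered series of frames sharing geometry and bit depth."""

    frames: list[ImageFrame]
    acquisition_times: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.frames:
            shape = self.frames[0].shape
            depth = self.frames[0].bit_depth
            for f in self.frames:
                if f.shape != shape or f.bit_depth != depth:
                    raise ValueError("all frames in a stack must share H, W and bit depth")
        if self.acquisition_times is not None and len(self.acquisition_times) != len(self.frames):
            raise ValueError("one acquisition time per frame required")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[ImageFrame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> ImageFrame:
        return self.frames[i]


@dataclass
class Region:
    """A labelled region: an axis-aligned half-open box, optionally with a mask.

    ``box`` is ``(row0, col0, row1, col1)`` with ``row1``/``col1`` exclusive.
    ``mask``, when given, is a boolean array of the box's shape selecting the
    member pixels.
    """

    label: str
    box: tuple[int, int, int, int]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.box
        if r1 <= r0 or c1 <= c0:
            raise ValueError(f"empty region box {self.box}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (r1 - r0, c1 - c0):
                raise ValueError("mask shape must match the box")
            if not self.mask.any():
                raise ValueError("region mask selects no pixels")

    @classmethod
    def disk(cls, label: str, center: tuple[float, float], radius: float) -> "Region":
        """A disk region around ``center=(row, col)`` of the given radius."""
        r0 = int(math.floor(center[0] - radius))
        c0 = int(math.floor(center[1] - radius))
        r1 = int(math.ceil(center[0] + radius)) + 1
        c1 = int(math.ceil(center[1] + radius)) + 1
        rr, cc = np.mgrid[r0:r1, c0:c1]
        mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
        return cls(label=label, box=(r0, c0, r1, c1), mask=mask)

    def clipped_to(self, shape: tuple[int, int]) -> "Region":
        """Clip the region to image bounds; raises if nothing remains."""
        r0, c0, r1, c1 = self.box
        nr0, nc0 = max(r0, 0), max(c0, 0)
        nr1, nc1 = min(r1, shape[0]), min(c1, shape[1])
        if nr1 <= nr0 or nc1 <= nc0:
            raise ValueError(f"region {self.label!r} lies outside the image")
        mask = self.mask
        if mask is not None:
            mask = mask[nr0 - r0 : nr1 - r0, nc0 - c0 : nc1 - c0]
            if not mask.any():
                raise ValueError(f"region {self.label!r} lies outside the image")
        return Region(label=self.label, box=(nr0, nc0, nr1, nc1), mask=mask)

    def is_clipped_by(self, shape: tuple[int, int]) -> bool:
        r0, c0, r1, c1 = self.box
        return r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]


def to_gray(frame: ImageFrame, weights: np.ndarray | None = None) -> np.ndarray:
    """Combine R, G, B into a single channel with Rec. 601 luma weights.

    The combination is linear and unrounded: ``0.299 R + 0.587 G + 0.114 B``.
    Custom ``weights`` may be supplied (they are used as given, not renormalized).
    """
    w = GRAY_WEIGHTS if weights is None else np.asarray(weights, dtype=float)
    return frame.pixels @ w


def stack_mean_std(stack: ImageStack) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and population std over every pixel of every frame.

    Statistics are pooled over space and time, which is the natural summary of
    a dark-frame series ("mean black level across the full resolution of the
    camera in a series of images").
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    data = np.stack([f.pixels for f in stack])  # N x H x W x 3
    means = data.mean(axis=(0, 1, 2))
    stds = data.std(axis=(0, 1, 2), ddof=0)
    return means, stds


def region_intensity(frame: ImageFrame, region: Region, channel: str = "gray") -> float:
    """Arithmetic mean of one channel over a region's pixels."""
    region = region.clipped_to(frame.shape)
    r0, c0, r1, c1 = region.box
    patch = frame.channel(channel)[r0:r1, c0:c1]
    if region.mask is not None:
        patch = patch[region.mask]
    return float(np.mean(patch))


def line_profile(
    frame: ImageFrame,
    start: tuple[float, float],
    end: tuple[float, float],
    channel: str = "gray",
) -> np.ndarray:
    """Intensity profile along a segment, bilinearly interpolated.

    ``start`` and ``end`` are ``(row, col)`` pixel coordinates (pixel centers
    at integers).  The segment is sampled at ``ceil(length) + 1`` evenly
    spaced points, i.e. at most unit-pixel spacing, so reversing the endpoints
    reverses the profile exactly.
    """
    H, W = frame.shape
    for name, (r, c) in (("start", start), ("end", end)):
        if not (0 <= r <= H - 1 and 0 <= c <= W - 1):
            raise ValueError(f"{name} point {r, c} outside image of shape {H, W}")
    length = math.hypot(end[0] - start[0], end[1] - start[1])
    n = int(math.ceil(length)) + 1
    rows = np.linspace(start[0], end[0], n)
    cols = np.linspace(start[1], end[1], n)
    img = frame.channel(channel)
    return ndimage.map_coordinates(img, np.vstack([rows, cols]), order=1, mode="nearest")
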