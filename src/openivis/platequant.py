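"""Well-plate geometry, per-well intensity extraction and flatness analysis.

A 96-well plate is modelled as a rectangular lattice of circular wells.  The
grid may be supplied (and locally refined against the image) or estimated from
the image autocorrelation.  Per-well statistics are means over a central disk,
optionally background-subtracted with a surrounding annulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import ImageFrame, Region

__all__ = [
    "PlateLayout",
    "Well",
    "WellGrid",
    "detect_grid",
    "well_intensities",
    "percent_deviation",
    "flat_field_correct",
]

ROW_LETTERS = "ABCDEFGHIJKLMNOP"


@dataclass(frozen=True)
class PlateLayout:
    """Logical plate geometry in pixel units.

    ``origin_px`` is the ``(row, col)`` pixel position of well A1's center;
    wells are spaced ``pitch_px`` apart in both directions.
    """

    n_rows: int = 8
    n_cols: int = 12
    pitch_px: float = 40.0
    well_radius_px: float = 14.0
    origin_px: tuple[float, float] = (40.0, 40.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("plate needs at least one well")
        if self.pitch_px <= 2 * self.well_radius_px * 0.9:
            raise ValueError("well pitch too small for the well radius")

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    def label(self, row: int, col: int) -> str:
        return f"{ROW_LETTERS[row]}{col + 1}"

    def centers(self) -> np.ndarray:
        """Lattice well centers, shape (n_rows, n_cols, 2) as (row, col) px."""
        rr = self.origin_px[0] + self.pitch_px * np.arange(self.n_rows)
        cc = self.origin_px[1] + self.pitch_px * np.arange(self.n_cols)
        grid = np.empty((self.n_rows, self.n_cols, 2))
        grid[..., 0] = rr[:, None]
        grid[..., 1] = cc[None, :]
        return grid

    def image_shape(self) -> tuple[int, int]:
        """A canvas that comfortably contains the plate."""
        h = int(round(self.origin_px[0] * 2 + self.pitch_px * (self.n_rows - 1)))
        w = int(round(self.origin_px[1] * 2 + self.pitch_px * (self.n_cols - 1)))
        return h, w


@dataclass
class Well:
    label: str
    row: int
    col: int
    center: tuple[float, float]
    region: Region


@dataclass
class WellGrid:
    """Detected per-well centers and regions, labelled A1..H12 row-major."""

    wells: list[Well]
    layout: PlateLayout
    disk_fraction: float = 0.8

    def __post_init__(self) -> None:
        if len(self.wells) != self.layout.n_wells:
            raise ValueError("grid must contain exactly n_rows*n_cols wells")

    def __len__(self) -> int:
        return len(self.wells)

    def __iter__(self):
        return iter(self.wells)

    def well(self, label: str) -> Well:
        for w in self.wells:
            if w.label == label:
                return w
        raise KeyError(label)

    def shifted(self, dy: float, dx: float) -> "WellGrid":
        wells = []
        for w in self.wells:
            c = (w.center[0] + dy, w.center[1] + dx)
            region = Region.disk(w.label, c, self.layout.well_radius_px * self.disk_fraction)
            wells.append(Well(w.label, w.row, w.col, c, region))
        return WellGrid(wells, self.layout, self.disk_fraction)


def _grid_from_centers(
    centers: np.ndarray, layout: PlateLayout, disk_fraction: float
) -> WellGrid:
    wells = []
    for r in range(layout.n_rows):
        for c in range(layout.n_cols):
            ctr = (float(centers[r, c, 0]), float(centers[r, c, 1]))
            label = layout.label(r, c)
            region = Region.disk(label, ctr, layout.well_radius_px * disk_fraction)
            wells.append(Well(label, r, c, ctr, region))
    return WellGrid(wells, layout, disk_fraction)


def _refine_center(
    img: np.ndarray, center: tuple[float, float], half: int, n_iter: int = 3
) -> tuple[tuple[float, float], bool]:
    """Iterated local intensity centroid around ``center``; returns (center, ok)."""
    H, W = img.shape
    current = center
    for _ in range(n_iter):
        r, c = int(round(current[0])), int(round(current[1]))
        r0, r1 = max(r - half, 0), min(r + half + 1, H)
        c0, c1 = max(c - half, 0), min(c + half + 1, W)
        patch = img[r0:r1, c0:c1]
        if patch.size == 0:
            return center, False
        # wells may be brighter or darker than their surround; weight |deviation|
        w = np.abs(patch - np.median(patch))
        total = w.sum()
        if total <= 0:
            return center, False
        rr, cc = np.mgrid[r0:r1, c0:c1]
        current = (float((w * rr).sum() / total), float((w * cc).sum() / total))
    return current, True


def _autocorr_pitch(img: np.ndarray) -> tuple[float, float]:
    """Lattice pitch along rows and columns from the image autocorrelation."""
    g = img - img.mean()
    f = np.fft.rfft2(g)
    acf = np.fft.irfft2(np.abs(f) ** 2, s=g.shape)
    pitches = []
    for axis_profile, n in ((acf[:, 0], g.shape[0]), (acf[0, :], g.shape[1])):
        prof = axis_profile[: n // 2]
        peaks, _ = find_peaks(prof, prominence=0.05 * prof.max())
        if len(peaks) == 0:
            raise ValueError("grid not found")
        # first significant autocorrelation peak = fundamental lattice period
        pitches.append(float(peaks[0]))
    return pitches[0], pitches[1]


def _fit_origin(
    img: np.ndarray, layout: PlateLayout
) -> tuple[float, float]:
    """Grid-search the lattice phase maximizing summed |deviation| at centers.

    The deviation image is averaged over a well-sized window first, so the
    objective peaks at well centers instead of plateauing across the disk.
    """
    from scipy.ndimage import uniform_filter

    dev = np.abs(img - np.median(img))
    dev = uniform_filter(dev, size=max(int(2 * layout.well_radius_px), 3))
    H, W = img.shape
    p = layout.pitch_px
    span_r = H - p * (layout.n_rows - 1)
    span_c = W - p * (layout.n_cols - 1)
    if span_r <= 0 or span_c <= 0:
        raise ValueError("grid not found")
    best, best_val = None, -np.inf
    for oy in np.arange(p / 2, span_r, 2.0):
        for ox in np.arange(p / 2, span_c, 2.0):
            rr = (oy + p * np.arange(layout.n_rows)).astype(int)
            cc = (ox + p * np.arange(layout.n_cols)).astype(int)
            val = dev[np.clip(rr, 0, H - 1)][:, np.clip(cc, 0, W - 1)].sum()
            if val > best_val:
                best_val, best = val, (float(oy), float(ox))
    return best


def detect_grid(
    frame: ImageFrame,
    layout: PlateLayout | None = None,
    channel: str = "gray",
    disk_fraction: float = 0.8,
    min_contrast: float = 1.0,
    max_fail_fraction: float = 0.10,
    min_found_fraction: float = 0.05,
) -> WellGrid:
    """Locate the well lattice in a plate image.

    With a ``layout``, the lattice centers are refined by a local intensity
    centroid within ``pitch/4`` of each nominal center.  Without one, the
    pitch is estimated from the autocorrelation peak spacing and the lattice
    phase by a grid search, assuming a standard 96-well (8x12) plate.

    Wells without local contrast (|disk mean - surround| < ``min_contrast``
    counts — e.g. empty or blank wells) keep their nominal lattice center.
    Among wells *with* contrast, a centroid refining away by more than
    ``pitch/4`` counts as a failure; more than ``max_fail_fraction`` failures,
    or fewer than ``min_found_fraction`` wells with contrast at all, raises
    ``ValueError("grid not found")``.
    """
    img = frame.channel(channel)
    if layout is None:
        pr, pc = _autocorr_pitch(img)
        pitch = (pr + pc) / 2
        trial = PlateLayout(pitch_px=pitch, well_radius_px=pitch * 0.35,
                            origin_px=(pitch / 2, pitch / 2))
        layout = PlateLayout(pitch_px=pitch, well_radius_px=pitch * 0.35,
                             origin_px=_fit_origin(img, trial))
    centers = layout.centers().copy()
    half = max(int(layout.pitch_px / 4), 2)
    # centroid window must straddle the well edge to see the well at all
    half_refine = max(int(layout.pitch_px * 0.45), 3)
    n_fail = 0
    n_found = 0
    for r in range(layout.n_rows):
        for c in range(layout.n_cols):
            nominal = (centers[r, c, 0], centers[r, c, 1])
            disk = Region.disk("w", nominal, layout.well_radius_px * disk_fraction)
            try:
                disk = disk.clipped_to(img.shape)
                r0, c0, r1, c1 = disk.box
                inner = img[r0:r1, c0:c1][disk.mask].mean()
                surround = np.median(
                    img[max(r0 - half, 0) : r1 + half, max(c0 - half, 0) : c1 + half]
                )
                has_contrast = abs(inner - surround) >= min_contrast
            except ValueError:
                has_contrast = False
            if not has_contrast:
                continue  # empty/blank well: keep the nominal lattice center
            n_found += 1
            refined, ok = _refine_center(img, nominal, half_refine)
            shift = np.hypot(refined[0] - nominal[0], refined[1] - nominal[1])
            if not ok or shift > layout.pitch_px / 4:
                n_fail += 1
            else:
                centers[r, c] = refined
    if n_found < max(min_found_fraction * layout.n_wells, 1.0):
        raise ValueError("grid not found")
    if n_fail > max_fail_fraction * max(n_found, 1):
        raise ValueError("grid not found")
    return _grid_from_centers(centers, layout, disk_fraction)


def well_intensities(
    frame: ImageFrame,
    grid: WellGrid,
    channel: str = "gray",
    background: str = "none",
) -> tuple[np.ndarray, list[str]]:
    """Mean counts over each well disk, row-major A1..H12.

    ``background='annulus'`` subtracts, per well, the median of an annulus at
    1.2-1.5 well radii and floors the result at zero.  Wells whose disk is
    clipped by the image edge are flagged (value still returned).

    Returns ``(values, flags)`` with one flag string ('' or 'edge-clipped')
    per well.
    """
    if background not in ("none", "annulus"):
        raise ValueError(f"unknown background mode {background!r}")
    img = frame.channel(channel)
    values = np.empty(len(grid))
    flags = []
    radius = grid.layout.well_radius_px
    for i, well in enumerate(grid):
        flag = ""
        region = well.region
        if region.is_clipped_by(img.shape):
            flag = "edge-clipped"
        region = region.clipped_to(img.shape)
        r0, c0, r1, c1 = region.box
        patch = img[r0:r1, c0:c1]
        v = float(patch[region.mask].mean() if region.mask is not None else patch.mean())
        if background == "annulus":
            outer = Region.disk(well.label, well.center, radius * 1.5).clipped_to(img.shape)
            inner = Region.disk(well.label, well.center, radius * 1.2).clipped_to(img.shape)
            ro0, co0, ro1, co1 = outer.box
            ann = np.zeros(img.shape, dtype=bool)
            ann[ro0:ro1, co0:co1] = outer.mask
            ri0, ci0, ri1, ci1 = inner.box
            ann[ri0:ri1, ci0:ci1] &= ~inner.mask
            v = max(v - float(np.median(img[ann])), 0.0)
        values[i] = v
        flags.append(flag)
    return values, flags


def percent_deviation(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-well percent deviation from the plate average, and max |deviation|.

    ``dev_i = 100 * (v_i - mean(v)) / mean(v)``; the deviation vector sums to
    zero by construction.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 wells")
    mean = values.mean()
    if mean <= 0:
        raise ValueError(f"plate mean must be positive, got {mean}")
    dev = 100.0 * (values - mean) / mean
    return dev, float(np.max(np.abs(dev)))


def flat_field_correct(frame: ImageFrame, field_map: np.ndarray) -> ImageFrame:
    """Divide out a known illumination field, preserving the mean level.

    ``corrected = frame * mean(field) / field``, clipped to the valid count
    range.  ``field_map`` must be strictly positive and match the frame shape.
    """
    field_map = np.asarray(field_map, dtype=float)
    if field_map.shape != frame.shape:
        raise ValueError("field shape must match the frame")
    if np.any(field_map <= 0):
        raise ValueError("illumination field must be strictly positive")
    scale = field_map.mean() / field_map
    corrected = np.clip(frame.pixels * scale[..., None], 0.0, frame.saturation)
    return frame.with_pixels(corrected)
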