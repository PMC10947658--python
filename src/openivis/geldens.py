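"""Gel electrophoresis densitometry.

Lane profiles (per-row mean across the lane width, optionally background
subtracted with a rolling minimum), band detection by peak prominence with
trapezoidal band areas, semilog migration fitting, and lane-to-lane
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import minimum_filter1d
from scipy.signal import find_peaks

from .core import ImageFrame, Region

__all__ = [
    "LaneProfile",
    "Band",
    "MigrationModel",
    "lane_profile",
    "detect_bands",
    "migration_fit",
    "compare_lanes",
]


@dataclass
class LaneProfile:
    """Background-subtracted intensity versus migration distance for one lane."""

    distances_px: np.ndarray  # from the well row, strictly increasing
    intensities: np.ndarray  # counts, >= 0 after subtraction
    label: str = ""
    load_amount: float | None = None

    def __post_init__(self) -> None:
        self.distances_px = np.asarray(self.distances_px, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(np.diff(self.distances_px) <= 0):
            raise ValueError("distances must be strictly increasing")
        if self.distances_px.shape != self.intensities.shape:
            raise ValueError("distances and intensities must match in length")
        if np.any(self.intensities < -1e-9):
            raise ValueError("profile intensities must be >= 0")

    def __len__(self) -> int:
        return len(self.intensities)


@dataclass
class Band:
    position_px: float
    area: float
    left_px: float
    right_px: float


@dataclass
class MigrationModel:
    """Semilog migration: ``position = a - b * log10(size_bp)`` with b > 0."""

    a: float
    b: float
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("migration slope b must be > 0 (smaller fragments travel farther)")

    def predict(self, sizes_bp) -> np.ndarray:
        return self.a - self.b * np.log10(np.asarray(sizes_bp, dtype=float))


def lane_profile(
    frame: ImageFrame,
    lane_box: Region,
    background: str = "rolling_min",
    window_px: int = 50,
    channel: str = "gray",
) -> LaneProfile:
    """Per-row mean intensity down a lane box.

    The box must be taller than wide (lanes run down the gel).  With
    ``background='rolling_min'`` a rolling minimum (default window 50 px) is
    subtracted and the result floored at zero; ``'none'`` keeps raw values.
    Distances are measured from the top of the box (the well row).
    """
    if background not in ("rolling_min", "none"):
        raise ValueError(f"unknown background mode {background!r}")
    r0, c0, r1, c1 = lane_box.box
    if lane_box.is_clipped_by(frame.shape):
        raise ValueError("lane box extends outside the image")
    if (r1 - r0) <= (c1 - c0):
        raise ValueError("lane box must be taller than wide")
    img = frame.channel(channel)
    prof = img[r0:r1, c0:c1].mean(axis=1)
    if background == "rolling_min":
        base = minimum_filter1d(prof, size=min(window_px, len(prof)))
        prof = np.maximum(prof - base, 0.0)
    return LaneProfile(
        distances_px=np.arange(len(prof), dtype=float),
        intensities=prof,
        label=lane_box.label,
    )


def detect_bands(profile: LaneProfile, prominence_frac: float = 0.05) -> list[Band]:
    """Bands as local maxima with prominence >= ``prominence_frac`` of range.

    Each band's area is the trapezoidal integral of the profile between its
    flanking minima (profile ends for the outermost bands).  A flat profile
    yields zero bands.
    """
    if len(profile) < 10:
        raise ValueError("profile too short (need >= 10 samples)")
    y = profile.intensities
    span = float(np.ptp(y))
    if span == 0:
        return []
    peaks, _ = find_peaks(y, prominence=prominence_frac * span)
    if len(peaks) == 0:
        return []
    # flanking minima between consecutive peaks; outermost bands extend to ends
    cuts = [0]
    for left, right in zip(peaks[:-1], peaks[1:]):
        cuts.append(int(left + np.argmin(y[left:right + 1])))
    cuts.append(len(y) - 1)
    bands = []
    for i, p in enumerate(peaks):
        lo, hi = cuts[i], cuts[i + 1]
        area = float(np.trapezoid(y[lo : hi + 1], profile.distances_px[lo : hi + 1]))
        bands.append(
            Band(
                position_px=float(profile.distances_px[p]),
                area=area,
                left_px=float(profile.distances_px[lo]),
                right_px=float(profile.distances_px[hi]),
            )
        )
    return bands


def migration_fit(band_positions_px, sizes_bp) -> MigrationModel:
    """Least-squares fit of ``position = a - b * log10(size)``."""
    pos = np.asarray(band_positions_px, dtype=float)
    sizes = np.asarray(sizes_bp, dtype=float)
    if pos.size != sizes.size:
        raise ValueError("positions and sizes must match in length")
    if pos.size < 3:
        raise ValueError("need at least 3 bands with known sizes")
    order = np.argsort(sizes)
    if np.any(np.diff(pos[order]) > 0):
        warnings.warn("band positions are not monotone in fragment size")
    X = np.column_stack([np.ones_like(sizes), -np.log10(sizes)])
    (a, b), res, *_ = np.linalg.lstsq(X, pos, rcond=None)
    fitted = X @ np.array([a, b])
    ss_res = float(np.sum((pos - fitted) ** 2))
    ss_tot = float(np.sum((pos - pos.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return MigrationModel(a=float(a), b=float(b), r_squared=r2)


def compare_lanes(
    p1: LaneProfile,
    p2: LaneProfile,
    prominence_frac: float = 0.05,
    match_tolerance_px: float = 5.0,
) -> dict:
    """Total and per-band intensity ratios between two lanes (lane2 / lane1).

    Bands are matched greedily to the nearest band within
    ``match_tolerance_px``.  Returns a dict with ``total_ratio``,
    ``band_ratios`` (list of (position1, position2, area_ratio)) and the
    unmatched band positions of each lane.
    """
    if len(p1) != len(p2):
        raise ValueError("profiles must share a length scale")
    s1, s2 = float(p1.intensities.sum()), float(p2.intensities.sum())
    if s1 == 0:
        raise ValueError("reference lane has zero total intensity")
    total_ratio = s2 / s1
    b1 = detect_bands(p1, prominence_frac)
    b2 = detect_bands(p2, prominence_frac)
    matches = []
    unmatched2 = list(range(len(b2)))
    unmatched1 = []
    for i, band in enumerate(b1):
        if not unmatched2:
            unmatched1.append(i)
            continue
        dists = [abs(b2[j].position_px - band.position_px) for j in unmatched2]
        jbest = int(np.argmin(dists))
        if dists[jbest] <= match_tolerance_px:
            j = unmatched2.pop(jbest)
            ratio = b2[j].area / band.area if band.area > 0 else float("nan")
            matches.append((band.position_px, b2[j].position_px, ratio))
        else:
            unmatched1.append(i)
    return {
        "total_ratio": total_ratio,
        "band_ratios": matches,
        "unmatched_lane1": [b1[i].position_px for i in unmatched1],
        "unmatched_lane2": [b2[j].position_px for j in unmatched2],
    }
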