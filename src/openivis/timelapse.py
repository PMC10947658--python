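"""Time-lapse specimen analysis: segmentation, size metrics, growth rate.

A specimen is segmented per frame by Otsu thresholding on the gray channel
(holes filled, largest connected component kept); the growth rate is the
slope of a least-squares fit of ln(area) versus time, i.e. an exponential
growth model, with a confidence interval from the residual variance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops

from .core import ImageFrame, ImageStack, Region, to_gray

__all__ = ["GrowthTrack", "segment_specimen", "growth_track"]


@dataclass
class GrowthTrack:
    timestamps_days: np.ndarray
    areas_px2: np.ndarray
    areas_mm2: np.ndarray | None
    major_axis_px: np.ndarray
    growth_rate_per_day: float
    growth_rate_ci: tuple[float, float]
    excluded_frames: list[int]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.timestamps_days) <= 0):
            raise ValueError("timestamps must be strictly increasing")


def segment_specimen(frame: ImageFrame, method: str = "otsu_on_gray") -> Region:
    """Segment the largest bright specimen against the background.

    Global Otsu threshold on the gray channel, hole filling, then the largest
    connected component.  Raises ``ValueError('no specimen')`` when nothing
    contrasts with the background.
    """
    if method != "otsu_on_gray":
        raise ValueError(f"unknown method {method!r}")
    gray = to_gray(frame)
    if np.ptp(gray) <= 1e-12:
        raise ValueError("no specimen: image has no contrast")
    thr = threshold_otsu(gray)
    fg = gray > thr
    if not fg.any():
        raise ValueError("no specimen: empty foreground")
    fg = ndimage.binary_fill_holes(fg)
    labels = sk_label(fg)
    props = regionprops(labels)
    biggest = max(props, key=lambda p: p.area)
    r0, c0, r1, c1 = biggest.bbox
    mask = labels[r0:r1, c0:c1] == biggest.label
    return Region(label="specimen", box=(r0, c0, r1, c1), mask=mask)


def _region_metrics(region: Region) -> tuple[float, float]:
    """(area px^2, major axis length px) of a segmented region."""
    props = regionprops(region.mask.astype(int))[0]
    return float(props.area), float(props.axis_major_length)


def growth_track(stack: ImageStack, model: str = "exponential") -> GrowthTrack:
    """Segment every frame and fit a growth model to the area series.

    ``model='exponential'`` fits ln(area) vs time by least squares; the rate
    is the slope (1/day) with a 95% CI from the residual variance.
    ``model='linear'`` fits area directly (rate in px^2/day).  Frames that
    fail segmentation are excluded with a warning.
    """
    if stack.acquisition_times is None:
        raise ValueError("stack needs acquisition timestamps")
    if len(stack) < 2:
        raise ValueError("need at least 2 frames")
    times, areas, majors, excluded = [], [], [], []
    pitch = stack[0].pixel_pitch_um
    for i, frame in enumerate(stack):
        try:
            region = segment_specimen(frame)
        except ValueError:
            warnings.warn(f"frame {i} failed segmentation; excluded")
            excluded.append(i)
            continue
        area, major = _region_metrics(region)
        times.append(float(stack.acquisition_times[i]))
        areas.append(area)
        majors.append(major)
    if len(times) < 2:
        raise ValueError("fewer than 2 frames segmented successfully")
    t = np.array(times)
    a = np.array(areas)
    if model == "exponential":
        y = np.log(a)
    elif model == "linear":
        y = a
    else:
        raise ValueError(f"unknown model {model!r}")
    fit = stats.linregress(t, y)
    n = len(t)
    if n > 2 and not math.isnan(fit.stderr):
        tcrit = stats.t.ppf(0.975, n - 2)
        ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    else:
        ci = (fit.slope, fit.slope)
    areas_mm2 = a * (pitch / 1000.0) ** 2 if pitch else None
    return GrowthTrack(
        timestamps_days=t,
        areas_px2=a,
        areas_mm2=areas_mm2,
        major_axis_px=np.array(majors),
        growth_rate_per_day=float(fit.slope),
        growth_rate_ci=(float(ci[0]), float(ci[1])),
        excluded_frames=excluded,
    )
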