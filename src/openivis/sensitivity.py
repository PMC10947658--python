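"""Exposure-sweep dose-response analysis for dilution plates.

Builds per-exposure response curves from a sweep of plate images, normalizes
them, estimates the limit of detection (blank + k.SD criterion with monotone
closure over concentrations), reports the quantifiable dynamic range per
exposure, recommends an exposure for a target concentration window, and fits
four-parameter logistic (4PL) calibration curves for ion-selective
nanosensors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .core import ImageStack
from .platequant import WellGrid, well_intensities

__all__ = [
    "ResponseCurve",
    "LodResult",
    "DynamicRange",
    "Fit4PL",
    "build_curves",
    "normalize",
    "detection_limit",
    "dynamic_range",
    "recommend_exposure",
    "sensor_calibration",
]


@dataclass
class ResponseCurve:
    """Replicate-well summary statistics per concentration per exposure.

    ``means``/``sds``/``ns`` have shape (n_exposures, n_concentrations);
    concentrations are stored in decreasing order.  Blank statistics come
    from wells mapped to concentration 0.
    """

    concentrations: np.ndarray  # M, strictly decreasing
    exposures_ms: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    ns: np.ndarray
    blank_means: np.ndarray  # per exposure
    blank_sds: np.ndarray
    blank_n: int
    saturation: float = 255.0

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if not (np.all(np.diff(c) < 0) or np.all(np.diff(c) > 0)):
            raise ValueError("concentrations must be strictly monotone")
        if self.means.shape != (len(self.exposures_ms), len(c)):
            raise ValueError("means must be n_exposures x n_concentrations")
        if np.any(self.ns < 1):
            raise ValueError("each (exposure, concentration) cell needs n >= 1")

    def exposure_index(self, exposure_ms: float) -> int:
        idx = np.nonzero(np.isclose(self.exposures_ms, exposure_ms))[0]
        if idx.size == 0:
            raise ValueError(f"exposure {exposure_ms} ms not in curve")
        return int(idx[0])

    def series(self, exposure_ms: float) -> np.ndarray:
        return self.means[self.exposure_index(exposure_ms)]


@dataclass
class LodResult:
    lod_molar: float | None  # None means "none detectable"
    exposure_ms: float | None
    threshold_counts: float | None
    detected: np.ndarray = field(default=None, repr=False)  # per (exposure, conc)

    @property
    def detectable(self) -> bool:
        return self.lod_molar is not None


def build_curves(
    stack: ImageStack,
    grid: WellGrid,
    plate_map: dict[str, float],
    channel: str = "gray",
    background: str = "annulus",
) -> ResponseCurve:
    """Group replicate wells per concentration per exposure frame.

    ``plate_map`` maps well labels to molar concentrations; wells mapped to
    exactly 0 are the blanks.  Every frame must carry exposure metadata.
    Replicate wells of one concentration must agree across frames (the plate
    does not move during the sweep).
    """
    if len(stack) == 0:
        raise ValueError("empty sweep")
    blanks = [lbl for lbl, c in plate_map.items() if c == 0.0]
    if not blanks:
        raise ValueError("plate map contains no blank wells (concentration 0)")
    concs = sorted({c for c in plate_map.values() if c > 0}, reverse=True)
    if not concs:
        raise ValueError("plate map contains no nonzero concentrations")
    exposures = np.array([f.setting.exposure_ms for f in stack])
    label_index = {w.label: i for i, w in enumerate(grid)}
    for lbl in plate_map:
        if lbl not in label_index:
            raise ValueError(f"plate map well {lbl!r} not present in the grid")
    means = np.empty((len(stack), len(concs)))
    sds = np.empty_like(means)
    ns = np.empty(means.shape, dtype=int)
    blank_means = np.empty(len(stack))
    blank_sds = np.empty(len(stack))
    for ei, frame in enumerate(stack):
        values, _ = well_intensities(frame, grid, channel=channel, background=background)
        for ci, conc in enumerate(concs):
            reps = [values[label_index[lbl]] for lbl, cc in plate_map.items() if cc == conc]
            means[ei, ci] = np.mean(reps)
            sds[ei, ci] = np.std(reps, ddof=0)
            ns[ei, ci] = len(reps)
        bvals = [values[label_index[lbl]] for lbl in blanks]
        blank_means[ei] = np.mean(bvals)
        blank_sds[ei] = np.std(bvals, ddof=0)
    return ResponseCurve(
        concentrations=np.array(concs),
        exposures_ms=exposures,
        means=means,
        sds=sds,
        ns=ns,
        blank_means=blank_means,
        blank_sds=blank_sds,
        blank_n=len(blanks),
        saturation=stack[0].saturation,
    )


def normalize(curve: ResponseCurve, mode: str = "max") -> ResponseCurve:
    """Normalize each exposure series to [0, 1].

    ``max`` divides by the series maximum; ``minmax`` maps min -> 0 and
    max -> 1 (errors on a constant series).
    """
    means = curve.means.astype(float).copy()
    sds = curve.sds.astype(float).copy()
    for ei in range(means.shape[0]):
        row = means[ei]
        if mode == "max":
            peak = row.max()
            if peak <= 0:
                raise ValueError("cannot max-normalize a nonpositive series")
            means[ei] = row / peak
            sds[ei] = sds[ei] / peak
        elif mode == "minmax":
            span = row.max() - row.min()
            if span == 0:
                raise ValueError("constant series cannot be minmax-normalized")
            means[ei] = (row - row.min()) / span
            sds[ei] = sds[ei] / span
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return ResponseCurve(
        concentrations=curve.concentrations,
        exposures_ms=curve.exposures_ms,
        means=means,
        sds=sds,
        ns=curve.ns,
        blank_means=curve.blank_means,
        blank_sds=curve.blank_sds,
        blank_n=curve.blank_n,
        saturation=curve.saturation,
    )


def detection_limit(curve: ResponseCurve, k: float = 3.0) -> LodResult:
    """Limit of detection by the blank + k.SD rule with monotone closure.

    A concentration is detected at an exposure when its mean exceeds
    ``blank_mean + k * blank_sd`` for that exposure.  The LOD is the smallest
    concentration detected at any exposure such that every larger tested
    concentration is also detected at some exposure (isolated noise-triggered
    detections below an undetected concentration are discarded).
    """
    thresholds = curve.blank_means + k * curve.blank_sds
    detected = curve.means > thresholds[:, None]
    any_exp = detected.any(axis=0)  # per concentration, decreasing c order
    lod_idx = None
    for ci in range(len(curve.concentrations)):
        if any_exp[ci]:
            lod_idx = ci
        else:
            break  # monotone closure: stop at the first undetected concentration
    if lod_idx is None:
        return LodResult(None, None, None, detected)
    exp_idx = int(np.nonzero(detected[:, lod_idx])[0][0])
    return LodResult(
        lod_molar=float(curve.concentrations[lod_idx]),
        exposure_ms=float(curve.exposures_ms[exp_idx]),
        threshold_counts=float(thresholds[exp_idx]),
        detected=detected,
    )


@dataclass
class DynamicRange:
    lowest_molar: float | None
    highest_molar: float | None
    decades: float

    @property
    def empty(self) -> bool:
        return self.lowest_molar is None


def dynamic_range(
    curve: ResponseCurve, exposure_ms: float, k: float = 3.0, saturation_guard: float = 0.9
) -> DynamicRange:
    """Quantifiable concentration span at one exposure.

    Lowest = smallest concentration above the detection threshold; highest =
    largest concentration whose mean stays below ``saturation_guard`` x full
    scale; decades = log10(highest / lowest).  An inverted span is empty.
    """
    ei = curve.exposure_index(exposure_ms)
    thr = curve.blank_means[ei] + k * curve.blank_sds[ei]
    sat = saturation_guard * curve.saturation
    concs = curve.concentrations
    det = curve.means[ei] > thr
    unsat = curve.means[ei] < sat
    if not det.any() or not unsat.any():
        return DynamicRange(None, None, 0.0)
    lowest = concs[det].min()
    highest = concs[unsat].max()
    if lowest > highest:
        return DynamicRange(None, None, 0.0)
    return DynamicRange(float(lowest), float(highest), float(np.log10(highest / lowest)))


def recommend_exposure(
    curve: ResponseCurve,
    target_range: tuple[float, float],
    k: float = 3.0,
    saturation_guard: float = 0.9,
) -> float:
    """Exposure maximizing target concentrations inside the quantifiable band.

    A concentration counts as covered when its mean lies strictly between the
    detection threshold and ``saturation_guard`` x full scale.  Ties go to the
    shorter exposure ("best dynamic range" formalized as coverage count).
    """
    c_lo, c_hi = min(target_range), max(target_range)
    in_target = (curve.concentrations >= c_lo) & (curve.concentrations <= c_hi)
    if not in_target.any():
        raise ValueError("target range contains no tested concentration")
    best_exposure, best_count = None, 0
    order = np.argsort(curve.exposures_ms)  # shorter exposures first for tie-break
    for ei in order:
        thr = curve.blank_means[ei] + k * curve.blank_sds[ei]
        sat = saturation_guard * curve.saturation
        covered = (curve.means[ei] > thr) & (curve.means[ei] < sat) & in_target
        n = int(covered.sum())
        if n > best_count:
            best_count, best_exposure = n, float(curve.exposures_ms[ei])
    if best_exposure is None:
        raise ValueError("no exposure covers any target concentration")
    return best_exposure


@dataclass
class Fit4PL:
    bottom: float
    top: float
    ec50_molar: float
    slope: float
    r_squared: float

    def predict(self, conc_molar) -> np.ndarray:
        x = np.log10(np.asarray(conc_molar, dtype=float))
        return _logistic4(x, self.bottom, self.top, math.log10(self.ec50_molar), self.slope)


def _logistic4(logc, bottom, top, log_ec50, slope):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - logc) * slope))


def sensor_calibration(
    curve: ResponseCurve, exposure_ms: float | None = None
) -> Fit4PL:
    """Least-squares 4PL fit of one exposure's response versus log10 c.

    The usual nanosensor calibration model ``y = bottom + (top - bottom) /
    (1 + 10**((log EC50 - log c) * slope))``.  Initialization: bottom/top
    from the series min/max, EC50 from the half-response crossing, slope sign
    from the overall trend.  Needs at least 5 concentrations spanning the
    transition; a flat series or a non-converging fit raises.
    """
    if exposure_ms is None:
        if len(curve.exposures_ms) != 1:
            raise ValueError("specify exposure_ms for a multi-exposure curve")
        exposure_ms = float(curve.exposures_ms[0])
    y = curve.series(exposure_ms).astype(float)
    c = curve.concentrations.astype(float)
    if len(c) < 5:
        raise ValueError("need at least 5 concentrations for a 4PL fit")
    if np.ptp(y) <= 1e-12 * max(abs(y).max(), 1.0):
        raise ValueError("flat response: no transition to fit")
    x = np.log10(c)
    order = np.argsort(x)
    x, y = x[order], y[order]
    y_lo, y_hi = float(y.min()), float(y.max())
    half = (y_lo + y_hi) / 2.0
    x_half = float(x[np.argmin(np.abs(y - half))])
    trend = np.polyfit(x, y, 1)[0]
    slope0 = 1.0 if trend >= 0 else -1.0
    try:
        popt, _ = curve_fit(
            _logistic4,
            x,
            y,
            p0=[y_lo, y_hi, x_half, slope0],
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"4PL fit did not converge: {exc}") from exc
    fitted = _logistic4(x, *popt)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return Fit4PL(
        bottom=float(popt[0]),
        top=float(popt[1]),
        ec50_molar=float(10.0 ** popt[2]),
        slope=float(popt[3]),
        r_squared=r2,
    )
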