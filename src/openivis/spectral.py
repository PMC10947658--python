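"""Long-pass filter-series spectral analysis and the anthocyanin index.

Imaging the same scene through a series of long-pass filters with increasing
cut-on wavelength yields, per region, a nonincreasing signal-versus-cut-on
curve; successive differences of that curve reconstruct the emission energy
in each inter-cut-on band.  The anthocyanin index compares fluorescence under
green versus red excitation through the same long-pass filter as a log ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .core import GRAY_WEIGHTS, ImageFrame, Region, region_intensity

__all__ = [
    "SpectralSeries",
    "BandSpectrum",
    "build_series",
    "channel_response",
    "band_reconstruct",
    "anthocyanin_index",
]

CHANNELS = ("R", "G", "B")


@dataclass
class SpectralSeries:
    """Per-region, per-channel mean signal versus long-pass cut-on wavelength."""

    cuton_nm: np.ndarray  # strictly increasing
    signals: dict[str, np.ndarray]  # label -> (n_cutons, 3) R,G,B means
    labels: list[str]

    def __post_init__(self) -> None:
        self.cuton_nm = np.asarray(self.cuton_nm, dtype=float)
        if np.any(np.diff(self.cuton_nm) <= 0):
            raise ValueError("cut-on wavelengths must be strictly increasing")
        for label, arr in self.signals.items():
            if arr.shape != (len(self.cuton_nm), 3):
                raise ValueError(f"signals for {label!r} must be n_cutons x 3")

    def channel_values(self, label: str, channel: str) -> np.ndarray:
        arr = self.signals[label]
        if channel == "gray":
            return arr @ GRAY_WEIGHTS
        return arr[:, CHANNELS.index(channel)]


@dataclass
class BandSpectrum:
    """Reconstructed emission energy per wavelength band for one region.

    ``bands`` is a list of ``(lambda_lo, lambda_hi, energy)``; the terminal
    band is open-ended (``lambda_hi = inf``).
    """

    label: str
    bands: list[tuple[float, float, float]]

    def total(self) -> float:
        return float(sum(b[2] for b in self.bands))


def build_series(
    frames,
    regions: list[Region],
) -> SpectralSeries:
    """Collect per-region, per-channel means across a long-pass filter series.

    Every frame must carry a long-pass ``filter_cuton_nm``; duplicate cut-ons
    are an error.  Framing must be identical across filters (the same region
    coordinates are applied to every frame).
    """
    frames = list(frames)
    if not frames:
        raise ValueError("empty filter series")
    if not regions:
        raise ValueError("no regions supplied")
    cutons = []
    for f in frames:
        s = f.setting
        if s.filter_cuton_nm is None or s.filter_kind != "longpass":
            raise ValueError("every frame needs a long-pass filter cut-on")
        cutons.append(s.filter_cuton_nm)
    if len(set(cutons)) != len(cutons):
        raise ValueError("duplicate filter cut-on in series")
    order = np.argsort(cutons)
    cutons = np.array(cutons, dtype=float)[order]
    signals = {}
    labels = []
    for reg in regions:
        vals = np.empty((len(frames), 3))
        for k, oi in enumerate(order):
            frame = frames[oi]
            for ch_i, ch in enumerate(CHANNELS):
                vals[k, ch_i] = region_intensity(frame, reg, channel=ch)
        signals[reg.label] = vals
        labels.append(reg.label)
    return SpectralSeries(cuton_nm=cutons, signals=signals, labels=labels)


def channel_response(
    series: SpectralSeries,
    channel: str,
    label: str | None = None,
    tol: float = 1e-9,
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Signal versus cut-on per region, repaired to be nonincreasing.

    An ideal long-pass series can only lose signal as the cut-on rises; noise
    can violate that, so an isotonic (nonincreasing) regression is applied
    and adjusted points are flagged.  Returns, per region label, a tuple
    ``(cuton_nm, values, flags)`` where ``flags[i]`` marks points the
    monotone repair moved by more than ``tol``.
    """
    labels = [label] if label is not None else series.labels
    iso = IsotonicRegression(increasing=False)
    out = {}
    for lbl in labels:
        raw = series.channel_values(lbl, channel)
        fitted = iso.fit_transform(series.cuton_nm, raw)
        flags = np.abs(fitted - raw) > tol
        out[lbl] = (series.cuton_nm.copy(), fitted, flags)
    return out


def band_reconstruct(
    series: SpectralSeries, label: str, channel: str = "gray"
) -> BandSpectrum:
    """Differential reconstruction of the emission spectrum from a LP series.

    With monotone signals ``S(lambda_i)``, the energy emitted between
    consecutive cut-ons is ``B_i = S(lambda_i) - S(lambda_{i+1})`` (floored at
    0) and the terminal open band carries ``S(lambda_n)``.  The band energies
    telescope: their sum equals the first cut-on's signal.
    """
    if len(series.cuton_nm) < 2:
        raise ValueError("need at least 2 cut-ons to reconstruct bands")
    resp = channel_response(series, channel, label=label)[label]
    cutons, values, _ = resp
    bands = []
    for i in range(len(cutons) - 1):
        energy = max(float(values[i] - values[i + 1]), 0.0)
        bands.append((float(cutons[i]), float(cutons[i + 1]), energy))
    bands.append((float(cutons[-1]), float("inf"), max(float(values[-1]), 0.0)))
    return BandSpectrum(label=label, bands=bands)


def anthocyanin_index(
    f_green_exc: ImageFrame,
    f_red_exc: ImageFrame,
    mask: np.ndarray | None = None,
    epsilon: float = 0.5,
    channel: str = "R",
) -> tuple[np.ndarray, float]:
    """Log fluorescence-excitation-ratio anthocyanin index map.

    Both frames are taken through the same long-pass filter, one under green
    (520 nm) and one under red (630 nm) excitation:

        AI = ln((F_red_exc + eps) / (F_green_exc + eps))

    ``eps`` (default 0.5 counts) guards the log for near-black pixels.  The
    exact index variant in the plant-stress literature varies; this log-ratio
    form matches the two acquisition conditions and is pluggable.  Returns
    the per-pixel map and the masked mean.
    """
    if f_green_exc.shape != f_red_exc.shape:
        raise ValueError("frames must share a shape (registered acquisition)")
    g = f_green_exc.channel(channel)
    r = f_red_exc.channel(channel)
    ai = np.log((r + epsilon) / (g + epsilon))
    if mask is None:
        return ai, float(ai.mean())
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ai.shape:
        raise ValueError("mask shape must match the frames")
    if not mask.any():
        raise ValueError("empty mask")
    return ai, float(ai[mask].mean())
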