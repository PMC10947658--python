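"""Readers and writers: PNG/TIFF frames, acquisition manifests, CSV tables.

Frames are stored in memory as float counts; quantization to uint8/uint16
happens only here, at file write.  A manifest is a JSON or YAML mapping of
filename to acquisition fields (``exposure_ms``, ``led``, ``drive``,
``filter_cuton_nm``, ``filter_kind``, ``filter_halfwidth_nm``, optionally
``time_days``).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import AcquisitionSetting, ImageFrame, ImageStack

__all__ = [
    "write_frame",
    "read_frame",
    "setting_from_dict",
    "setting_to_dict",
    "read_manifest",
    "write_manifest",
    "load_stack",
    "save_stack",
    "profile_to_csv",
]


def write_frame(path: str | Path, frame: ImageFrame) -> None:
    """Write a frame as 8-bit PNG or 8/16-bit TIFF (by extension)."""
    path = Path(path)
    data = np.clip(np.round(frame.pixels), 0, frame.saturation)
    if path.suffix.lower() == ".png":
        if frame.bit_depth > 8:
            raise ValueError("PNG output supports 8-bit frames only")
        iio.imwrite(path, data.astype(np.uint8))
    elif path.suffix.lower() in (".tif", ".tiff"):
        dtype = np.uint8 if frame.bit_depth <= 8 else np.uint16
        tifffile.imwrite(path, data.astype(dtype))
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")


def read_frame(
    path: str | Path,
    setting: AcquisitionSetting | None = None,
    pixel_pitch_um: float | None = None,
) -> ImageFrame:
    """Read a PNG/TIFF into float counts; bit depth inferred from the dtype."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = np.repeat(data[..., None], 3, axis=2)
    if data.shape[2] == 4:  # drop alpha
        data = data[..., :3]
    bit_depth = 16 if data.dtype == np.uint16 else 8
    return ImageFrame(
        pixels=data.astype(float),
        bit_depth=bit_depth,
        setting=setting or AcquisitionSetting(),
        pixel_pitch_um=pixel_pitch_um,
    )


def setting_from_dict(d: dict) -> AcquisitionSetting:
    if "exposure_ms" not in d:
        raise ValueError("manifest entry missing exposure_ms")
    return AcquisitionSetting(
        exposure_ms=float(d["exposure_ms"]),
        led_channel=d.get("led", "off"),
        drive_level=float(d.get("drive", 1.0)),
        filter_cuton_nm=(None if d.get("filter_cuton_nm") is None
                         else float(d["filter_cuton_nm"])),
        filter_kind=d.get("filter_kind", "longpass"),
        filter_halfwidth_nm=(None if d.get("filter_halfwidth_nm") is None
                             else float(d["filter_halfwidth_nm"])),
    )


def setting_to_dict(s: AcquisitionSetting) -> dict:
    return {
        "exposure_ms": s.exposure_ms,
        "led": s.led_channel,
        "drive": s.drive_level,
        "filter_cuton_nm": s.filter_cuton_nm,
        "filter_kind": s.filter_kind,
        "filter_halfwidth_nm": s.filter_halfwidth_nm,
    }


def read_manifest(path: str | Path) -> dict[str, dict]:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError("manifest must map filenames to acquisition fields")
    return data


def write_manifest(path: str | Path, entries: dict[str, dict]) -> None:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(entries, sort_keys=False))
    else:
        path.write_text(json.dumps(entries, indent=2))


def load_stack(manifest_path: str | Path) -> ImageStack:
    """Read all frames listed in a manifest (paths relative to the manifest)."""
    manifest_path = Path(manifest_path)
    entries = read_manifest(manifest_path)
    frames, times = [], []
    has_times = False
    for fname, fields in entries.items():
        setting = setting_from_dict(fields)
        frames.append(read_frame(manifest_path.parent / fname, setting=setting))
        if "time_days" in fields:
            has_times = True
            times.append(float(fields["time_days"]))
        else:
            times.append(float("nan"))
    return ImageStack(frames=frames, acquisition_times=times if has_times else None)


def save_stack(
    out_dir: str | Path,
    stack: ImageStack,
    prefix: str = "frame",
    fmt: str = "png",
) -> Path:
    """Write every frame plus a JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = {}
    for i, frame in enumerate(stack):
        fname = f"{prefix}_{i:03d}.{fmt}"
        write_frame(out_dir / fname, frame)
        fields = setting_to_dict(frame.setting)
        if stack.acquisition_times is not None:
            fields["time_days"] = stack.acquisition_times[i]
        entries[fname] = fields
    manifest = out_dir / "manifest.json"
    write_manifest(manifest, entries)
    return manifest


def profile_to_csv(path: str | Path, distances, intensities, **extra_cols) -> None:
    df = pd.DataFrame({"distance_px": distances, "intensity": intensities, **extra_cols})
    df.to_csv(path, index=False)
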