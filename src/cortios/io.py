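"""Readers and writers for stacks, sidecar metadata, logs, and ROI files.

Formats are deliberately plain: multi-page grayscale TIFF (16-bit) or raw
little-endian 16-bit binary for frame stacks, JSON sidecars for acquisition
metadata and provenance, CSV for trigger logs / ROI tables / results, and a
YAML key-value file for CLI configuration.

The raw-binary dialect is little-endian unsigned 16-bit, frame-major
(frame 0 first, rows within a frame in row-major order); a sidecar is
mandatory because the file itself carries no shape information.
"""

from __future__ import annotations

import json
import os
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError
from .types import FrameStack, RoiSpec, StimulusSchedule

__all__ = [
    "write_stack",
    "read_stack",
    "sidecar_path",
    "write_sidecar",
    "read_sidecar",
    "write_trigger_log",
    "read_trigger_log",
    "read_rois",
    "write_rois",
    "read_polylines",
    "write_polylines",
    "load_config",
]

DEFAULT_FRAME_RATE = 132.82
DEFAULT_PIXEL_PITCH = 7.5

RAW_SUFFIXES = {".raw", ".bin"}
TIFF_SUFFIXES = {".tif", ".tiff"}


# ---------------------------------------------------------------------------
# sidecar metadata
# ---------------------------------------------------------------------------

def sidecar_path(stack_path: str | Path) -> Path:
    return Path(str(stack_path) + ".json")


def write_sidecar(stack: FrameStack, path: str | Path) -> None:
    meta = {
        "height_px": int(stack.frame_shape[0]),
        "width_px": int(stack.frame_shape[1]),
        "n_frames": int(stack.n_frames),
        "frame_rate_fps": float(stack.frame_rate_fps),
        "pixel_pitch_um": float(stack.pixel_pitch_um),
        "bit_depth": int(stack.bit_depth),
        "provenance": stack.meta,
    }
    Path(path).write_text(json.dumps(meta, indent=2, default=str))


def read_sidecar(path: str | Path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"sidecar {path} is not valid JSON: {exc}") from exc


# ---------------------------------------------------------------------------
# frame stacks
# ---------------------------------------------------------------------------

def _to_uint(data: np.ndarray, bit_depth: int) -> np.ndarray:
    hi = 2 ** bit_depth - 1
    return np.rint(np.clip(data, 0, hi)).astype("<u2")


def write_stack(stack: FrameStack, path: str | Path,
                sidecar: str | Path | None = None) -> Path:
    """Write a stack as multi-page TIFF (.tif/.tiff) or raw binary (.raw/.bin).

    Values are rounded and clipped to the unsigned range of ``bit_depth``
    and stored as little-endian 16-bit.  A JSON sidecar (metadata +
    provenance) is always written next to the stack.
    """
    path = Path(path)
    frames = _to_uint(np.moveaxis(stack.data, 2, 0), stack.bit_depth)
    if path.suffix.lower() in TIFF_SUFFIXES:
        tifffile.imwrite(path, frames, photometric="minisblack")
    elif path.suffix.lower() in RAW_SUFFIXES:
        frames.tofile(path)
    else:
        raise FormatError(f"unsupported stack extension {path.suffix!r}")
    write_sidecar(stack, sidecar or sidecar_path(path))
    return path


def read_stack(path: str | Path, sidecar: str | Path | None = None) -> FrameStack:
    """Read a TIFF or raw stack, attaching sidecar metadata.

    Raw files require a sidecar for their shape; a file size that is not a
    whole number of frames is a :class:`FormatError` naming the byte offset
    where the truncation occurs.  TIFF stacks fall back to default frame
    rate / pixel pitch with a warning when no sidecar is present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    side = Path(sidecar) if sidecar else sidecar_path(path)
    meta = read_sidecar(side) if side.exists() else None

    if path.suffix.lower() in TIFF_SUFFIXES:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    elif path.suffix.lower() in RAW_SUFFIXES:
        if meta is None:
            raise FormatError(f"raw stack {path} requires a sidecar "
                              f"({side} not found)")
        H, W = int(meta["height_px"]), int(meta["width_px"])
        frame_bytes = H * W * 2
        size = os.path.getsize(path)
        n, rem = divmod(size, frame_bytes)
        if rem or n == 0:
            raise FormatError(
                f"raw stack {path} truncated: {size} bytes is not a whole "
                f"number of {frame_bytes}-byte frames (cut at byte {n * frame_bytes})")
        frames = np.fromfile(path, dtype="<u2").reshape(n, H, W)
    else:
        raise FormatError(f"unsupported stack extension {path.suffix!r}")

    if meta is None:
        warnings.warn(f"no sidecar for {path}; assuming defaults "
                      f"{DEFAULT_FRAME_RATE} fps, {DEFAULT_PIXEL_PITCH} um",
                      stacklevel=2)
        meta = {"frame_rate_fps": DEFAULT_FRAME_RATE,
                "pixel_pitch_um": DEFAULT_PIXEL_PITCH, "bit_depth": 16}
    else:
        expect = (int(meta["n_frames"]), int(meta["height_px"]),
                  int(meta["width_px"]))
        if frames.shape != expect:
            raise FormatError(
                f"stack shape {frames.shape} does not match sidecar {expect}")

    return FrameStack(data=np.moveaxis(frames, 0, 2).astype(float),
                      frame_rate_fps=float(meta["frame_rate_fps"]),
                      pixel_pitch_um=float(meta["pixel_pitch_um"]),
                      bit_depth=int(meta.get("bit_depth", 16)),
                      meta=meta.get("provenance", {}))


# ---------------------------------------------------------------------------
# trigger logs
# ---------------------------------------------------------------------------

def write_trigger_log(schedule: StimulusSchedule, path: str | Path,
                      frame_rate_fps: float) -> Path:
    onsets = np.asarray(schedule.onset_frames)
    pd.DataFrame({
        "trial_index": np.arange(onsets.size),
        "onset_frame": onsets,
        "onset_time_s": onsets / frame_rate_fps,
        "duration_s": schedule.duration_s,
    }).to_csv(path, index=False)
    return Path(path)


def read_trigger_log(path: str | Path, frame_rate_fps: float | None = None,
                     default_duration_s: float = 1.5) -> StimulusSchedule:
    """Parse a trigger CSV into a schedule.

    Accepts either an ``onset_frame`` column or an ``onset_time_s`` column
    (converted with ``frame_rate_fps``, rounding to the nearest frame).
    Onsets are sorted and deduplicated; duration defaults to
    ``default_duration_s`` when absent.  An empty log is an error.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"trigger log {path} is empty") from None
    if "onset_frame" in df.columns:
        onsets = df["onset_frame"].to_numpy(dtype=float)
    elif "onset_time_s" in df.columns:
        if frame_rate_fps is None:
            raise ValueError("onset_time_s log requires frame_rate_fps")
        onsets = df["onset_time_s"].to_numpy(dtype=float) * frame_rate_fps
    else:
        raise ValueError(f"trigger log {path} has no onset_frame or "
                         "onset_time_s column")
    if onsets.size == 0:
        raise ValueError(f"trigger log {path} contains no onsets")
    frames = np.unique(np.rint(onsets).astype(int))
    if frames.size < onsets.size:
        warnings.warn(f"trigger log {path}: duplicate onsets removed",
                      stacklevel=2)
    duration = float(df["duration_s"].iloc[0]) if "duration_s" in df.columns \
        else default_duration_s
    return StimulusSchedule(onset_frames=tuple(frames), duration_s=duration)


# ---------------------------------------------------------------------------
# ROI files
# ---------------------------------------------------------------------------

def write_rois(rois: list[RoiSpec], path: str | Path) -> Path:
    rows = []
    for roi in rois:
        if roi.kind != "rect":
            raise ValueError("write_rois handles rectangular ROIs; "
                             "use write_polylines for lines")
        r, c, h, w = roi.rect
        rows.append({"label": roi.label, "row": r, "col": c,
                     "height": h, "width": w})
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_rois(path: str | Path) -> list[RoiSpec]:
    """Rectangular ROIs from CSV (columns: label, row, col, height, width)."""
    df = pd.read_csv(path)
    required = {"label", "row", "col"}
    if not required.issubset(df.columns):
        raise ValueError(f"ROI file {path} needs columns {sorted(required)}")
    out = []
    for _, rec in df.iterrows():
        out.append(RoiSpec.rectangle(int(rec["row"]), int(rec["col"]),
                                     int(rec.get("height", 20)),
                                     int(rec.get("width", 20)),
                                     label=str(rec["label"])))
    return out


def write_polylines(lines: list[RoiSpec], path: str | Path) -> Path:
    rows = []
    for line in lines:
        for r, c in line.points:
            rows.append({"label": line.label, "row": r, "col": c})
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_polylines(path: str | Path) -> list[RoiSpec]:
    """Vessel polylines from CSV (label, row, col; ordered within each label)
    or JSON (``[{"label": ..., "points": [[row, col], ...]}, ...]``)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        blocks = json.loads(path.read_text())
        return [RoiSpec.line(b["points"], label=str(b.get("label", i)))
                for i, b in enumerate(blocks)]
    df = pd.read_csv(path)
    if not {"label", "row", "col"}.issubset(df.columns):
        raise ValueError(f"polyline file {path} needs label,row,col columns")
    lines = []
    for label, grp in df.groupby("label", sort=False):
        lines.append(RoiSpec.line(grp[["row", "col"]].to_numpy(float),
                                  label=str(label)))
    return lines


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Flat key-value configuration from a YAML file."""
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a key-value mapping")
    return data
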