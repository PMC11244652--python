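"""File formats: TIFF stacks with JSON sidecars, ROI/geometry JSON, CSV traces.

Image stacks travel as multi-frame TIFF (uint8/uint16/float32) with a sidecar
JSON carrying acquisition metadata (``timestamps_s``, ``pixel_size_um``,
``channel``) — chosen over TIFF tag parsing for portability.  Geometry and
run configs accept JSON or YAML.  Every CLI run writes a provenance record
(config + package version + seed) next to its outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .inversion import FitResult
from .trafficking import ImageStack, QuantError, RegionOfInterest

SIDECAR_SUFFIX = ".meta.json"


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(tiff_path.suffix + SIDECAR_SUFFIX)


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a multi-frame TIFF plus its metadata sidecar JSON."""
    path = Path(path)
    frames = stack.frames
    if frames.dtype not in (np.uint8, np.uint16, np.float32):
        frames = frames.astype(np.float32)
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta = {
        "timestamps_s": [float(t) for t in stack.timestamps_s],
        "pixel_size_um": float(stack.pixel_size_um),
        "channel": stack.channel,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_stack(path: str | Path) -> ImageStack:
    """Read a multi-frame TIFF and its sidecar; validates frame/time counts."""
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None, ...]
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    times = meta.get("timestamps_s")
    if times is None or len(times) != len(frames):
        raise FormatError(
            f"{path}: {len(frames)} frames but "
            f"{'no' if times is None else len(times)} timestamps in sidecar"
        )
    try:
        return ImageStack(
            frames=frames,
            timestamps_s=np.asarray(times, dtype=float),
            pixel_size_um=float(meta["pixel_size_um"]),
            channel=meta.get("channel", ""),
        )
    except (KeyError, QuantError) as exc:
        raise FormatError(f"{path}: invalid stack metadata: {exc}") from exc


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(mask, dtype=np.uint8) * 255)


def read_mask(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise FormatError(f"{path}: mask must be a single 2D frame")
    return arr > 0


def write_rois(path: str | Path, rois: list[RegionOfInterest]) -> None:
    payload = [
        {"label": r.label, "vertices_um": r.vertices_um.tolist()} for r in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_rois(path: str | Path) -> list[RegionOfInterest]:
    payload = json.loads(Path(path).read_text())
    try:
        return [
            RegionOfInterest(label=r["label"], vertices_um=np.asarray(r["vertices_um"]))
            for r in payload
        ]
    except (KeyError, TypeError, QuantError) as exc:
        raise FormatError(f"{path}: invalid ROI file: {exc}") from exc


def read_geometry_config(path: str | Path) -> dict:
    """Load a channel-graph geometry description from JSON or YAML."""
    text = Path(path).read_text()
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: cannot parse geometry config: {exc}") from exc
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: geometry config must be a mapping")
    return cfg


def read_trace_csv(path: str | Path) -> pd.DataFrame:
    """Read a trace CSV: (time_s, value) or (time_s, distance_um, value).

    Times must be sorted ascending (per distance, when distances are given).
    """
    df = pd.read_csv(path)
    if "time_s" not in df or "value" not in df:
        raise FormatError(f"{path}: need columns time_s and value")
    groups = df.groupby("distance_um") if "distance_um" in df else [(None, df)]
    for key, grp in groups:
        if np.any(np.diff(grp["time_s"].to_numpy()) < 0):
            where = "" if key is None else f" (distance {key})"
            raise FormatError(
                f"{path}: time_s is not sorted{where}; sort rows by time_s first"
            )
    return df


def write_trace_csv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def write_fit_result(path: str | Path, fit: FitResult) -> None:
    payload = asdict(fit)
    payload["residuals"] = [None if np.isnan(r) else float(r) for r in fit.residuals]
    payload["bounds"] = list(fit.bounds)
    Path(path).write_text(json.dumps(payload, indent=2))


def write_json(path: str | Path, obj) -> None:
    def default(o):
        if is_dataclass(o):
            return asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))


def write_provenance(out_dir: str | Path, subcommand: str, config: dict, seed: int | None = None) -> Path:
    """Record how a run was produced: config, package version, seed, time."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "tool": "dermaflux",
        "version": __version__,
        "subcommand": subcommand,
        "config": config,
        "seed": seed,
        "written_utc": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / f"provenance_{subcommand.replace('-', '_')}.json"
    write_json(path, record)
    return path
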