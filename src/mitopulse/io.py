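"""Readers and writers: trace CSV, image + sidecar, JSON results.

All machine-readable outputs are JSON (with a schema version) or CSV; images
travel as 16-bit TIFF or PNG rasters with a JSON sidecar carrying the
physical pixel size, without which areas would be meaningless.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio

from mitopulse.images import MitoImage
from mitopulse.traces import LuminescenceTrace

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_image",
    "write_image",
    "write_label_raster",
    "read_label_raster",
    "write_results",
    "config_hash",
]

RESULTS_SCHEMA_VERSION = 1


def read_trace_csv(path) -> LuminescenceTrace:
    """Read a luminescence trace from CSV with header ``time_h,counts``.

    Times must form a uniform grid (the bin width is inferred from the
    spacing) and counts must be non-negative integers; violations are
    reported with the offending line number (1-based, counting the header).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != ["time_h", "counts"]:
        raise ValueError(f"{path}: expected header 'time_h,counts', got {list(df.columns)}")
    if len(df) < 2:
        raise ValueError(f"{path}: need at least 2 rows to infer the bin width")
    for i, v in enumerate(df["counts"]):
        line = i + 2
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{path}, line {line}: counts must be non-negative (got {v})")
        if float(v) != int(v):
            raise ValueError(f"{path}, line {line}: counts must be integers (got {v})")
    times = df["time_h"].to_numpy(dtype=float)
    dt = np.diff(times)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
        bad = int(np.argmax(~np.isclose(dt, dt[0], rtol=1e-6))) + 3
        raise ValueError(f"{path}, line {bad}: non-uniform time grid")
    bin_s = float(dt[0] * 3600.0)
    return LuminescenceTrace(
        times=times,
        counts=df["counts"].to_numpy(dtype=float),
        bin_s=bin_s,
        meta={"source": str(path)},
    )


def write_trace_csv(trace: LuminescenceTrace, path) -> Path:
    """Write a trace as ``time_h,counts`` CSV (counts rounded to integers)."""
    path = Path(path)
    df = pd.DataFrame(
        {"time_h": trace.times, "counts": np.rint(trace.counts).astype(np.int64)}
    )
    df.to_csv(path, index=False)
    return path


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_image(path, sidecar=None) -> MitoImage:
    """Read a TIFF/PNG raster with its JSON sidecar into a MitoImage.

    The sidecar (default ``<image>.<ext>.json``) must provide
    ``pixel_size_um``; without it areas cannot be expressed in µm².
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar}: pixel_size_um is required to interpret areas"
        )
    meta = json.loads(sidecar.read_text())
    if "pixel_size_um" not in meta:
        raise ValueError(f"{sidecar}: sidecar lacks pixel_size_um")
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        pixels = iio.imread(path)
    return MitoImage(pixels=pixels, pixel_size_um=float(meta["pixel_size_um"]), meta=meta)


def write_image(img: MitoImage, path, extra_meta: dict | None = None) -> Path:
    """Write a MitoImage as 16-bit TIFF/PNG plus a JSON sidecar."""
    path = Path(path)
    pixels = np.asarray(img.pixels)
    if pixels.dtype != np.uint16:
        pixels = np.clip(np.rint(pixels), 0, 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels)
    else:
        iio.imwrite(path, pixels)
    meta = {"pixel_size_um": img.pixel_size_um}
    meta.update(extra_meta or {})
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, default=_jsonable))
    return path


def write_label_raster(labels: np.ndarray, path) -> Path:
    """Write an integer label raster as TIFF (lossless round trip)."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32))
    return path


def read_label_raster(path) -> np.ndarray:
    return tifffile.imread(Path(path))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_results(obj: dict, path) -> Path:
    """Write a results dict as versioned JSON."""
    path = Path(path)
    payload = {"schema_version": RESULTS_SCHEMA_VERSION, **obj}
    path.write_text(json.dumps(payload, indent=2, default=_jsonable))
    return path


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration dict, for run logging."""
    blob = json.dumps(config, sort_keys=True, default=_jsonable).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
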