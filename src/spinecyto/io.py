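"""File I/O: TIFF images with µm calibration, trace/ROI CSVs, result tables.

Conventions: coordinates in µm, 0-based pixel indices, half-open ROI
intervals; CSV is comma-separated UTF-8 with '.' decimal and header
comment lines prefixed '#'.  Pixel size resolution order: TIFF metadata,
sidecar YAML (<image>.yaml with key ``pixel_um``), config override —
a missing calibration is an explicit error, never a silent default.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .config import RunConfig
from .geometry import FilamentTrace, ProtrusionTrack
from .periodicity import ImageGrid, RoiBox

__all__ = [
    "CalibrationError",
    "TraceFormatError",
    "read_image",
    "write_image",
    "read_rois",
    "read_traces",
    "write_traces",
    "write_results",
    "read_results",
]

log = logging.getLogger("spinecyto")

TRACE_COLUMNS = [
    "trace_id", "cell_id", "side", "frame_time_min",
    "point_index", "x_um", "y_um", "z_um",
]


class CalibrationError(ValueError):
    """No µm pixel size could be determined for an image."""


class TraceFormatError(ValueError):
    """A trace CSV violates the schema or its invariants."""


# --------------------------------------------------------------------------
# images


def _pixel_um_from_tiff(tif: tifffile.TiffFile) -> Optional[float]:
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" in tags:
        num, den = tags["XResolution"].value
        if num:
            unit_um = None
            ij = tif.imagej_metadata or {}
            if ij.get("unit") in ("um", "micron", "µm"):
                unit_um = 1.0
            elif "ResolutionUnit" in tags:
                ru = tags["ResolutionUnit"].value
                ru = getattr(ru, "value", ru)
                if ru == 3:  # centimetre
                    unit_um = 1e4
                elif ru == 2:  # inch
                    unit_um = 25.4e3
            if unit_um is not None:
                return den / num * unit_um
    return None


def read_image(path, config: Optional[RunConfig] = None) -> ImageGrid:
    """Load a single-channel TIFF with its µm calibration."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        values = tif.asarray().astype(float)
        pixel_um = _pixel_um_from_tiff(tif)
    if values.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2D image")
    if pixel_um is None:
        sidecar = path.with_suffix(".yaml")
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = yaml.safe_load(fh) or {}
            pixel_um = meta.get("pixel_um")
    if pixel_um is None and config is not None:
        pixel_um = config.pixel_um
    if pixel_um is None:
        raise CalibrationError(
            f"{path}: no pixel size in TIFF metadata or sidecar YAML and no "
            "config override; supply pixel_um explicitly"
        )
    return ImageGrid(values, float(pixel_um))


def write_image(image: ImageGrid, path) -> None:
    """Write a 16-bit TIFF with the pixel size in ImageJ metadata and a
    sidecar YAML (<image>.yaml)."""
    path = Path(path)
    values = image.values
    lo, hi = float(values.min()), float(values.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    data = np.round((values - lo) * scale).astype(np.uint16)
    res = 1.0 / image.pixel_um
    tifffile.imwrite(
        path, data, imagej=True, resolution=(res, res),
        metadata={"unit": "um"},
    )
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(
            {"pixel_um": image.pixel_um, "intensity_offset": lo,
             "intensity_scale": scale},
            fh,
        )


# --------------------------------------------------------------------------
# ROIs and traces


def read_rois(path) -> list[RoiBox]:
    """ROI list CSV: image, side, z_index, dv_start_um, dv_end_um, width_um."""
    df = pd.read_csv(path, comment="#")
    required = {"side", "z_index", "dv_start_um", "dv_end_um", "width_um"}
    missing = required - set(df.columns)
    if missing:
        raise TraceFormatError(f"ROI CSV missing columns: {sorted(missing)}")
    return [
        RoiBox(
            dv_start_um=row.dv_start_um,
            dv_end_um=row.dv_end_um,
            width_um=row.width_um,
            side=row.side,
            z_index=int(row.z_index),
            ab_start_um=getattr(row, "ab_start_um", 0.0),
        )
        for row in df.itertuples()
    ]


def read_traces(path):
    """Load a trace CSV into FilamentTrace / ProtrusionTrack collections.

    One point per row (schema ``TRACE_COLUMNS``); rows may arrive in any
    order, the parsed object is restored from the indices.  Returns
    ``(traces, tracks)``: single-frame traces (empty frame_time_min) and
    multi-frame tracks grouped by trace_id.
    """
    df = pd.read_csv(path, comment="#")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise TraceFormatError(
            f"trace CSV missing columns: {sorted(missing)}"
        )
    dup = df.duplicated(subset=["trace_id", "frame_time_min", "point_index"],
                        keep=False)
    if dup.any():
        raise TraceFormatError(
            "duplicate (trace_id, frame_time_min, point_index) rows"
        )
    traces: list[FilamentTrace] = []
    tracks: list[ProtrusionTrack] = []
    for trace_id, group in df.groupby("trace_id", sort=True):
        frames = []
        for t_min, pts in group.groupby("frame_time_min", sort=True,
                                        dropna=False):
            pts = pts.sort_values("point_index")
            frames.append(
                FilamentTrace(
                    points=pts[["x_um", "y_um", "z_um"]].to_numpy(),
                    cell_id=pts["cell_id"].iloc[0],
                    side=str(pts["side"].iloc[0]),
                    frame_time_min=None if pd.isna(t_min) else float(t_min),
                )
            )
        if len(frames) == 1 and frames[0].frame_time_min is None:
            traces.append(frames[0])
        else:
            times = [f.frame_time_min for f in frames]
            if any(t is None for t in times):
                raise TraceFormatError(
                    f"trace {trace_id}: mixed timed and untimed frames"
                )
            diffs = np.diff(times)
            if len(diffs) and np.any(diffs <= 0):
                raise TraceFormatError(
                    f"trace {trace_id}: non-monotone frame times"
                )
            interval = float(diffs[0]) if len(diffs) else 2.0
            tracks.append(
                ProtrusionTrack(traces=frames, frame_interval_min=interval)
            )
    return traces, tracks


def write_traces(items, path) -> None:
    """Write traces/tracks back to the one-point-per-row CSV schema."""
    rows = []
    for i, item in enumerate(items):
        frames = item.traces if isinstance(item, ProtrusionTrack) else [item]
        for tr in frames:
            for j, (x, y, z) in enumerate(tr.points):
                rows.append(
                    {
                        "trace_id": i,
                        "cell_id": tr.cell_id,
                        "side": tr.side,
                        "frame_time_min": tr.frame_time_min,
                        "point_index": j,
                        "x_um": x, "y_um": y, "z_um": z,
                    }
                )
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)


# --------------------------------------------------------------------------
# result tables


def write_results(
    table: pd.DataFrame, path, config: Optional[RunConfig] = None
) -> None:
    """Write a tidy CSV with config hash and seed as '#' header comments.

    Deterministic: same table and config give a byte-identical file.
    """
    path = Path(path)
    buf = _io.StringIO()
    if config is not None:
        buf.write(f"# config_hash: {config.hash()}\n")
        buf.write(f"# seed: {config.seed}\n")
    table.to_csv(buf, index=False)
    path.write_text(buf.getvalue(), encoding="utf-8")
    log.info("wrote %d rows to %s", len(table), path)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
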