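"""File contracts: TIFF images/stacks, ROI files, spot and track tables.

Scenes are written as ``(C, Y, X)`` TIFFs and movies as ``(T, C, Y, X)``;
calibration travels in the config/manifest rather than in TIFF tags. ROIs
are JSON polygons (``{"polygon": [[row, col], ...]}``) with a small reader
for ImageJ ``.roi`` rectangles and polygons.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import CellROI, Image2D, ImageStack
from .detection import SPOT_COLUMNS, SpotSet

__all__ = [
    "read_image",
    "write_image",
    "read_stack",
    "write_stack",
    "read_roi_json",
    "write_roi_json",
    "read_imagej_roi",
    "read_spots_csv",
    "write_spots_csv",
    "write_tracks_csv",
]


def read_image(path: str | Path, pixel_size: float, channel: int = 0, channel_name: str = "") -> Image2D:
    """Read one channel of a 2-D or (C, Y, X) TIFF."""
    data = tifffile.imread(str(path))
    if data.ndim == 3:
        data = data[channel]
    elif data.ndim != 2:
        raise ValueError(f"expected 2-D or (C, Y, X) TIFF, got shape {data.shape}")
    return Image2D(np.asarray(data, dtype=float), pixel_size, channel_name)


def write_image(path: str | Path, *channels: np.ndarray) -> None:
    """Write channel arrays as a (C, Y, X) float32 TIFF (2-D when single)."""
    stackable = np.stack([np.asarray(c, dtype=np.float32) for c in channels])
    tifffile.imwrite(str(path), stackable[0] if len(channels) == 1 else stackable)


def read_stack(
    path: str | Path, pixel_size: float, frame_interval: float, channel: int = 0, channel_name: str = ""
) -> ImageStack:
    """Read one channel of a (T, Y, X) or (T, C, Y, X) TIFF time series."""
    data = tifffile.imread(str(path))
    if data.ndim == 4:
        data = data[:, channel]
    elif data.ndim != 3:
        raise ValueError(f"expected (T, Y, X) or (T, C, Y, X) TIFF, got shape {data.shape}")
    return ImageStack(np.asarray(data, dtype=float), pixel_size, frame_interval, channel_name)


def write_stack(path: str | Path, data: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(data, dtype=np.float32))


def read_roi_json(path: str | Path) -> CellROI:
    with open(path) as fh:
        payload = json.load(fh)
    return CellROI(np.asarray(payload["polygon"], dtype=float))


def write_roi_json(path: str | Path, roi: CellROI) -> None:
    with open(path, "w") as fh:
        json.dump({"polygon": roi.polygon.tolist()}, fh)


def read_imagej_roi(path: str | Path) -> CellROI:
    """Decode an ImageJ ``.roi`` file (rectangle or polygon types only)."""
    raw = Path(path).read_bytes()
    if raw[:4] != b"Iout":
        raise ValueError("not an ImageJ ROI file")
    roi_type = raw[6]
    top, left, bottom, right = struct.unpack(">4h", raw[8:16])
    n_coords = struct.unpack(">h", raw[16:18])[0]
    if roi_type == 1:  # rectangle
        return CellROI(
            np.array(
                [[top, left], [top, right - 1], [bottom - 1, right - 1], [bottom - 1, left]],
                dtype=float,
            )
        )
    if roi_type in (0, 3):  # polygon / freehand
        xs = struct.unpack(f">{n_coords}h", raw[64 : 64 + 2 * n_coords])
        ys = struct.unpack(f">{n_coords}h", raw[64 + 2 * n_coords : 64 + 4 * n_coords])
        verts = [[top + y, left + x] for x, y in zip(xs, ys)]
        return CellROI(np.asarray(verts, dtype=float))
    raise ValueError(f"unsupported ImageJ ROI type {roi_type}")


def read_spots_csv(path: str | Path) -> SpotSet:
    return SpotSet(pd.read_csv(path))


def write_spots_csv(path: str | Path, spots: SpotSet) -> None:
    spots.table.to_csv(path, index=False, columns=SPOT_COLUMNS, float_format="%.6f")


def write_tracks_csv(path: str | Path, tracks, metrics: pd.DataFrame) -> None:
    """Long-format track table: one row per (track, frame) with summary columns."""
    rows = []
    for tid, tr in enumerate(tracks.tracks):
        met = metrics.iloc[tid]
        for f, (r, c) in zip(tr.frames, tr.positions):
            rows.append(
                {
                    "track_id": tid,
                    "frame": int(f),
                    "row": float(r),
                    "col": float(c),
                    "v_um_s": float(met["v_um_s"]),
                    "L_um": float(met["L_um"]),
                }
            )
    pd.DataFrame(rows, columns=["track_id", "frame", "row", "col", "v_um_s", "L_um"]).to_csv(
        path, index=False, float_format="%.6f"
    )
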