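"""Calibrated image containers and cell ROI geometry.

Coordinates are 0-based ``(row, col)`` with pixel centers at integer
positions. Physical calibration is carried alongside the arrays so that
every downstream statistic can be reported in micrometers and seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Image2D", "ImageStack", "CellROI", "make_roi_mask"]


@dataclass
class Image2D:
    """A single calibrated grayscale frame.

    Parameters
    ----------
    intensity : ndarray
        2-D array of finite, non-negative intensities.
    pixel_size : float
        Pixel pitch in µm/px; must be positive.
    channel_name : str
        Free-text channel label (e.g. ``"fa"`` or ``"cargo"``).
    """

    intensity: np.ndarray
    pixel_size: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2-D array")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclass
class ImageStack:
    """An ordered single-channel time series of frames.

    ``data`` has shape ``(T, H, W)``; all frames share ``pixel_size``.
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack data must be (T, H, W)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def frame(self, t: int) -> Image2D:
        return Image2D(self.data[t], self.pixel_size, self.channel_name)


def _polygon_area(vertices: np.ndarray) -> float:
    r = vertices[:, 0]
    c = vertices[:, 1]
    return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))


def _segments_cross(p1, p2, q1, q2) -> bool:
    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return int(v > 0) - int(v < 0)

    o1, o2 = orient(p1, p2, q1), orient(p1, p2, q2)
    o3, o4 = orient(q1, q2, p1), orient(q1, q2, p2)
    return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)


@dataclass
class CellROI:
    """Cell region of interest as a simple polygon in pixel coordinates.

    Vertices are ``(row, col)`` pairs; at least three are required, the
    polygon must have positive area and may not self-intersect.
    """

    polygon: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2:
            raise ValueError("polygon must be an (N, 2) array of (row, col)")
        if len(self.polygon) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if _polygon_area(self.polygon) <= 0:
            raise ValueError("degenerate polygon (zero area)")
        n = len(self.polygon)
        for i in range(n):
            for j in range(i + 1, n):
                if abs(i - j) in (1, n - 1):  # adjacent edges share a vertex
                    continue
                if _segments_cross(
                    self.polygon[i],
                    self.polygon[(i + 1) % n],
                    self.polygon[j],
                    self.polygon[(j + 1) % n],
                ):
                    raise ValueError("polygon is self-intersecting")


def make_roi_mask(roi: CellROI, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon ROI to a boolean mask.

    A pixel is inside when its *center* (integer coordinate) is inside the
    polygon under the even-odd rule; the half-open crossing convention
    resolves centers lying exactly on an edge deterministically.
    """
    verts = roi.polygon
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    pr = rr.ravel()
    pc = cc.ravel()
    inside = np.zeros(pr.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        r1, c1 = verts[i]
        r2, c2 = verts[(i + 1) % n]
        if r1 == r2:
            continue
        straddles = (r1 > pr) != (r2 > pr)
        with np.errstate(invalid="ignore"):
            c_at = c1 + (pr - r1) * (c2 - c1) / (r2 - r1)
        inside ^= straddles & (pc < c_at)
    return inside.reshape(shape)
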