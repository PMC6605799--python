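"""Segmentation and spot-level quantification.

Objects are segmented by Gaussian smoothing followed by a global threshold
(explicit or Otsu computed over ROI pixels only). Diffraction-limited spots
are found as prominence-filtered local maxima with deterministic
brighter-wins / lexicographic conflict resolution, a reproducible stand-in
for interactive maxima picking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .core import CellROI, Image2D, make_roi_mask  # noqa: F401  (re-export)

__all__ = [
    "LabelMask",
    "SpotSet",
    "make_roi_mask",
    "segment_objects",
    "detect_spots",
    "count_objects",
    "spot_density",
    "normalized_spot_intensity",
]

SPOT_COLUMNS = ["frame", "row", "col", "peak", "mean", "area"]


@dataclass
class LabelMask:
    """Labeled segmentation result with segmentation provenance.

    ``labels`` is an integer image where 0 is background and objects are
    numbered contiguously ``1..n_objects``; ``sigma_used`` and
    ``threshold_used`` record the parameters that produced it.
    """

    labels: np.ndarray
    n_objects: int
    sigma_used: float
    threshold_used: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = np.unique(self.labels)
        present = present[present > 0]
        if len(present) != self.n_objects or (
            len(present) and not np.array_equal(present, np.arange(1, self.n_objects + 1))
        ):
            raise ValueError("labels must be contiguous 1..n_objects")

    def areas(self) -> np.ndarray:
        """Pixel area of each object, index k-1 for label k."""
        if self.n_objects == 0:
            return np.zeros(0, dtype=int)
        return np.bincount(self.labels.ravel(), minlength=self.n_objects + 1)[1:]

    def as_binary(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class SpotSet:
    """Table of detected spots: one row per (frame, centroid)."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=SPOT_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"spot table missing columns {missing}")
        self.table = self.table[SPOT_COLUMNS].reset_index(drop=True)
        if self.table.duplicated(subset=["frame", "row", "col"]).any():
            raise ValueError("duplicate (frame, centroid) records")

    def __len__(self) -> int:
        return len(self.table)

    def positions(self) -> np.ndarray:
        return self.table[["row", "col"]].to_numpy(dtype=float)

    def in_frame(self, t: int) -> "SpotSet":
        return SpotSet(self.table[self.table["frame"] == t])

    @property
    def frames(self) -> np.ndarray:
        return np.unique(self.table["frame"].to_numpy())


def segment_objects(
    image: Image2D,
    roi_mask: np.ndarray,
    sigma: float = 1.0,
    threshold: float | str = "otsu",
) -> LabelMask:
    """Segment bright objects inside the ROI.

    Smooths with a Gaussian of ``sigma`` px, thresholds (Otsu computed over
    ROI pixels when ``threshold == "otsu"``), restricts to the ROI, and
    labels 8-connected components. A threshold above the smoothed maximum
    yields a valid empty mask.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != image.shape:
        raise ValueError("image and ROI mask shapes differ")
    if not roi_mask.any():
        raise ValueError("empty ROI")

    smoothed = ndi.gaussian_filter(image.intensity, sigma) if sigma > 0 else image.intensity
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        roi_vals = smoothed[roi_mask]
        thr = float(roi_vals.min()) if np.ptp(roi_vals) == 0 else float(threshold_otsu(roi_vals))
    else:
        thr = float(threshold)

    binary = (smoothed > thr) & roi_mask
    labels, n = ndi.label(binary, structure=np.ones((3, 3), dtype=int))
    return LabelMask(labels=labels, n_objects=int(n), sigma_used=float(sigma), threshold_used=thr)


def _refine_centroid(smoothed: np.ndarray, peak: tuple[int, int], radius: int = 2) -> tuple[float, float]:
    """Background-subtracted intensity-weighted centroid in a small window."""
    h, w = smoothed.shape
    r0, r1 = max(peak[0] - radius, 0), min(peak[0] + radius + 1, h)
    c0, c1 = max(peak[1] - radius, 0), min(peak[1] + radius + 1, w)
    win = smoothed[r0:r1, c0:c1] - smoothed[r0:r1, c0:c1].min()
    total = win.sum()
    if total == 0:
        return float(peak[0]), float(peak[1])
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    return float((win * rr).sum() / total), float((win * cc).sum() / total)


def detect_spots(
    image: Image2D,
    roi_mask: np.ndarray | None = None,
    min_distance: int = 3,
    prominence: float = 10.0,
    frame_index: int = 0,
) -> SpotSet:
    """Detect diffraction-limited spots as prominent local maxima.

    The image is lightly smoothed (sigma 1 px); candidate maxima are kept
    when they exceed the local background (windowed minimum) by more than
    ``prominence``. Conflicting candidates closer than ``min_distance`` are
    resolved brighter-first, ties by lower (row, col).
    """
    if min_distance < 1:
        raise ValueError("min_distance must be >= 1")
    if prominence <= 0:
        raise ValueError("prominence must be positive")
    intensity = image.intensity
    if roi_mask is None:
        roi_mask = np.ones(intensity.shape, dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != intensity.shape:
        raise ValueError("image and ROI mask shapes differ")

    smoothed = ndi.gaussian_filter(intensity, 1.0)
    # local background: windowed minimum over a region larger than one spot
    bg_size = 2 * max(2 * min_distance, 5) + 1
    local_bg = ndi.minimum_filter(smoothed, size=bg_size, mode="nearest")

    is_max = smoothed == ndi.maximum_filter(smoothed, size=3, mode="nearest")
    candidates = is_max & roi_mask & (smoothed - local_bg > prominence)
    rows, cols = np.nonzero(candidates)
    if len(rows) == 0:
        return SpotSet()

    values = smoothed[rows, cols]
    order = np.lexsort((cols, rows, -values))  # brighter first, then (row, col)
    rows, cols = rows[order], cols[order]

    accepted: list[tuple[int, int]] = []
    for r, c in zip(rows, cols):
        if all((r - ar) ** 2 + (c - ac) ** 2 >= min_distance**2 for ar, ac in accepted):
            accepted.append((int(r), int(c)))

    records = []
    h, w = intensity.shape
    for r, c in accepted:
        cr, cc = _refine_centroid(smoothed, (r, c))
        r0, r1 = max(r - 2, 0), min(r + 3, h)
        c0, c1 = max(c - 2, 0), min(c + 3, w)
        win = intensity[r0:r1, c0:c1]
        records.append(
            {
                "frame": frame_index,
                "row": cr,
                "col": cc,
                "peak": float(intensity[r, c]),
                "mean": float(win.mean()),
                "area": int(win.size),
            }
        )
    table = pd.DataFrame.from_records(records, columns=SPOT_COLUMNS)
    table = table.sort_values(["frame", "row", "col"], kind="stable").reset_index(drop=True)
    return SpotSet(table)


def count_objects(mask: LabelMask, min_area: int = 0) -> int:
    """Number of labeled objects whose pixel area is at least ``min_area``."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    return int(np.count_nonzero(mask.areas() >= min_area))


def spot_density(
    spots: SpotSet, roi_mask: np.ndarray, pixel_size: float
) -> tuple[int, float]:
    """Spot count inside the ROI, per cell and per µm² of ROI area."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    n_roi = int(roi_mask.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if len(spots) == 0:
        return 0, 0.0
    pos = np.rint(spots.positions()).astype(int)
    valid = (
        (pos[:, 0] >= 0)
        & (pos[:, 0] < roi_mask.shape[0])
        & (pos[:, 1] >= 0)
        & (pos[:, 1] < roi_mask.shape[1])
    )
    per_cell = int(np.count_nonzero(roi_mask[pos[valid, 0], pos[valid, 1]]))
    area_um2 = n_roi * pixel_size**2
    return per_cell, per_cell / area_um2


def normalized_spot_intensity(
    image: Image2D, spot_mask: np.ndarray, roi_mask: np.ndarray
) -> float:
    """Mean intensity over spot pixels divided by mean over all ROI pixels."""
    spot_mask = np.asarray(spot_mask, dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if spot_mask.shape != image.shape or roi_mask.shape != image.shape:
        raise ValueError("mask shapes must match the image")
    if not roi_mask.any():
        raise ValueError("empty ROI")
    if not spot_mask.any():
        raise ValueError("no secreted spots")
    if np.any(spot_mask & ~roi_mask):
        raise ValueError("spot mask extends outside the ROI")
    roi_mean = float(image.intensity[roi_mask].mean())
    if roi_mean == 0:
        raise ValueError("ROI mean intensity is zero")
    return float(image.intensity[spot_mask].mean()) / roi_mean
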