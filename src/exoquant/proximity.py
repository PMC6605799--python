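"""Distance-to-adhesion enrichment statistic.

The core spatial readout: for every pixel, the exact Euclidean distance to
the nearest focal-adhesion pixel; cargo-object pixels are histogrammed over
those distances and compared with the whole-ROI baseline distribution,
giving a per-bin enrichment ratio R(b). R(b) = 1 everywhere means the cargo
is placed with no spatial bias relative to the adhesions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "DistanceMap",
    "EnrichmentProfile",
    "distance_to_fa",
    "enrichment_profile",
    "enrichment_near",
]


@dataclass
class DistanceMap:
    """Per-pixel Euclidean distance (µm) to the nearest FA pixel center."""

    dist: np.ndarray
    pixel_size: float


@dataclass
class EnrichmentProfile:
    """Binned cargo vs. baseline distance distributions and their ratio.

    ``ratio`` is NaN where the baseline bin is empty (flagged, not zero).
    """

    bin_edges: np.ndarray  # length n_bins + 1, µm
    p_cargo: np.ndarray
    p_roi: np.ndarray
    ratio: np.ndarray
    n_cargo_px: int
    n_roi_px: int

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def n_bins(self) -> int:
        return len(self.p_roi)


def distance_to_fa(fa_mask: np.ndarray, pixel_size: float) -> DistanceMap:
    """Exact Euclidean distance from every pixel center to the nearest FA pixel."""
    fa_mask = np.asarray(fa_mask, dtype=bool)
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if not fa_mask.any():
        raise ValueError("no FA pixels")
    dist_px = ndi.distance_transform_edt(~fa_mask)
    return DistanceMap(dist=dist_px * pixel_size, pixel_size=pixel_size)


def enrichment_profile(
    cargo_mask: np.ndarray,
    fa_mask: np.ndarray,
    roi_mask: np.ndarray,
    pixel_size: float,
    bin_width: float = 0.5,
    exclude_fa_overlap: bool = False,
) -> EnrichmentProfile:
    """Histogram cargo and baseline FA-distances into uniform µm bins.

    Bins are ``[k*w, (k+1)*w)`` up to the largest observed ROI distance;
    both histograms are normalized to fractions and divided bin-wise.
    FA-overlapping cargo pixels count in the first bin unless
    ``exclude_fa_overlap`` removes them.
    """
    cargo_mask = np.asarray(cargo_mask, dtype=bool)
    fa_mask = np.asarray(fa_mask, dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not (cargo_mask.shape == fa_mask.shape == roi_mask.shape):
        raise ValueError("mask shapes differ")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if np.any(cargo_mask & ~roi_mask):
        raise ValueError("cargo pixel outside ROI")
    if exclude_fa_overlap:
        cargo_mask = cargo_mask & ~fa_mask
    if not cargo_mask.any():
        raise ValueError("no cargo signal")
    if not roi_mask.any():
        raise ValueError("empty ROI")

    dmap = distance_to_fa(fa_mask, pixel_size)  # raises on empty FA mask
    roi_d = dmap.dist[roi_mask]
    cargo_d = dmap.dist[cargo_mask]

    n_bins = int(np.floor(roi_d.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    # np.histogram closes the last bin; pad the final edge so the maximum
    # distance stays in its half-open bin [k*w, (k+1)*w).
    hist_edges = edges.copy()
    hist_edges[-1] = np.nextafter(edges[-1], np.inf)
    roi_counts, _ = np.histogram(roi_d, bins=hist_edges)
    cargo_counts, _ = np.histogram(cargo_d, bins=hist_edges)

    p_roi = roi_counts / roi_counts.sum()
    p_cargo = cargo_counts / cargo_counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p_roi > 0, p_cargo / np.where(p_roi > 0, p_roi, 1.0), np.nan)
    return EnrichmentProfile(
        bin_edges=edges,
        p_cargo=p_cargo,
        p_roi=p_roi,
        ratio=ratio,
        n_cargo_px=int(cargo_counts.sum()),
        n_roi_px=int(roi_counts.sum()),
    )


def enrichment_near(profile: EnrichmentProfile, d_cut: float) -> float:
    """Scalar enrichment within ``d_cut``: cargo fraction over baseline fraction.

    ``d_cut`` must be a positive multiple of the profile's bin width.
    """
    w = profile.bin_width
    if d_cut <= 0:
        raise ValueError("d_cut must be positive")
    k = d_cut / w
    if abs(k - round(k)) > 1e-9:
        raise ValueError("d_cut must be a multiple of the bin width")
    sel = profile.bin_edges[:-1] < d_cut - 1e-12 * max(d_cut, 1.0)
    roi_frac = profile.p_roi[sel].sum()
    if roi_frac == 0:
        raise ValueError("no ROI pixels within d_cut")
    return float(profile.p_cargo[sel].sum() / roi_frac)
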