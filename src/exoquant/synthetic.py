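"""Seeded synthetic two-channel scenes and vesicle movies with ground truth.

Scenes emulate TIRF-like geometry: an adhesion channel containing elongated
blobs oriented radially near the cell edge, and a cargo channel of
diffraction-limited spots placed either at controlled distances from the
adhesions (``fa_proximal``), uniformly over the cell (``uniform`` control),
or on the adhesions themselves (``on_fa``). Movies move point emitters
along polyline paths at constant programmed speed. Rendering uses a
Gaussian PSF, Poisson shot noise on signal plus background, and additive
Gaussian read noise. A single integer seed makes every output bit-identical
across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage as ndi

from .core import CellROI, Image2D, ImageStack, make_roi_mask

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cell_scene",
    "simulate_vesicle_movie",
]

CARGO_MODES = ("fa_proximal", "uniform", "on_fa")
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))

# fixed stream tags so that adding stages never perturbs earlier draws
_STREAM_FA = 1
_STREAM_CARGO = 2
_STREAM_NOISE_FA = 3
_STREAM_NOISE_CARGO = 4
_STREAM_TRACKS = 5
_STREAM_NOISE_MOVIE = 6


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


@dataclass
class SimulationConfig:
    """Parameters of one synthetic scene or movie.

    ``roi`` is either ``{"type": "ellipse", "center": (r, c), "radii": (ry, rx)}``
    or ``{"type": "polygon", "vertices": [[r, c], ...]}``; by default an
    ellipse filling most of the frame. ``fa_length_px``/``fa_width_px`` are
    full widths at half maximum of the anisotropic adhesion blobs;
    ``offset_scale_um`` is the scale d0 of the half-normal boundary offset
    used by ``fa_proximal`` cargo.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.1
    seed: int = 0
    roi: dict[str, Any] | None = None
    n_fas: int = 20
    fa_length_px: float = 12.0
    fa_width_px: float = 4.0
    cargo_mode: str = "fa_proximal"
    offset_scale_um: float = 0.5
    n_spots: int = 100
    spot_sigma_px: float = 1.5
    amplitude: float = 200.0
    background: float = 10.0
    gaussian_read_noise_sd: float = 2.0
    n_vesicles: int = 10
    n_frames: int = 30
    frame_interval_s: float = 0.2
    speed_um_s: float = 0.5
    tracks_share_paths: bool = False

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if min(self.n_fas, self.n_spots, self.n_vesicles) < 0:
            raise ValueError("entity counts must be >= 0")
        if self.cargo_mode not in CARGO_MODES:
            raise ValueError(f"cargo_mode must be one of {CARGO_MODES}")
        if self.offset_scale_um <= 0:
            raise ValueError("offset_scale_um must be positive")
        if self.speed_um_s < 0:
            raise ValueError("speed_um_s must be >= 0")
        if self.roi is None:
            h, w = self.image_shape
            self.roi = {
                "type": "ellipse",
                "center": ((h - 1) / 2.0, (w - 1) / 2.0),
                "radii": (0.42 * h, 0.42 * w),
            }


@dataclass
class GroundTruth:
    """Noiseless geometry behind a rendered scene or movie."""

    fa_mask: np.ndarray | None = None
    fa_centroids: list[tuple[float, float]] = field(default_factory=list)
    spot_centers: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    spot_fa_distances_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    tracks: list[np.ndarray] = field(default_factory=list)
    track_speeds_um_s: list[float] = field(default_factory=list)


def _roi_mask_from_spec(roi: dict[str, Any], shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    kind = roi.get("type")
    if kind == "ellipse":
        cr, cc = roi["center"]
        ry, rx = roi["radii"]
        if cr - ry < -0.5 or cc - rx < -0.5 or cr + ry > h - 0.5 or cc + rx > w - 0.5:
            raise ValueError("ROI outside image bounds")
        rr, ccg = np.mgrid[0:h, 0:w]
        return ((rr - cr) / ry) ** 2 + ((ccg - cc) / rx) ** 2 <= 1.0
    if kind == "polygon":
        verts = np.asarray(roi["vertices"], dtype=float)
        if verts[:, 0].min() < -0.5 or verts[:, 1].min() < -0.5:
            raise ValueError("ROI outside image bounds")
        if verts[:, 0].max() > h - 0.5 or verts[:, 1].max() > w - 0.5:
            raise ValueError("ROI outside image bounds")
        return make_roi_mask(CellROI(verts), shape)
    raise ValueError(f"unknown ROI type {kind!r}")


def _half_max_ellipse(
    shape: tuple[int, int], center: tuple[float, float], theta: float,
    length_px: float, width_px: float,
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    u = math.cos(theta) * dr + math.sin(theta) * dc
    v = -math.sin(theta) * dr + math.cos(theta) * dc
    return (u / (length_px / 2.0)) ** 2 + (v / (width_px / 2.0)) ** 2 <= 1.0


def _add_anisotropic_gaussian(
    image: np.ndarray, center: tuple[float, float], theta: float,
    sigma_u: float, sigma_v: float, amplitude: float,
) -> None:
    h, w = image.shape
    reach = int(math.ceil(4 * max(sigma_u, sigma_v)))
    r0 = max(int(center[0]) - reach, 0)
    r1 = min(int(center[0]) + reach + 1, h)
    c0 = max(int(center[1]) - reach, 0)
    c1 = min(int(center[1]) + reach + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = rr - center[0]
    dc = cc - center[1]
    u = math.cos(theta) * dr + math.sin(theta) * dc
    v = -math.sin(theta) * dr + math.cos(theta) * dc
    image[r0:r1, c0:c1] += amplitude * np.exp(
        -(u**2) / (2 * sigma_u**2) - (v**2) / (2 * sigma_v**2)
    )


def _add_spot(image: np.ndarray, center: tuple[float, float], sigma: float, amplitude: float) -> None:
    _add_anisotropic_gaussian(image, center, 0.0, sigma, sigma, amplitude)


def _place_fas(
    config: SimulationConfig, roi_mask: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[float, float]], list[float]]:
    """Rejection-sample non-overlapping radial blobs in a peripheral band."""
    h, w = config.image_shape
    edt_in = ndi.distance_transform_edt(roi_mask)
    max_depth = edt_in.max()
    lo = min(2.0, 0.05 * max_depth)
    hi = max(lo + 1.0, 0.35 * max_depth)
    band = roi_mask & (edt_in >= lo) & (edt_in <= hi)
    margin = config.fa_length_px
    rr, cc = np.mgrid[0:h, 0:w]
    band &= (rr >= margin) & (rr < h - margin) & (cc >= margin) & (cc < w - margin)
    band_pixels = np.argwhere(band)
    if config.n_fas > 0 and len(band_pixels) == 0:
        raise ValueError("ROI too small to place FAs")

    # inward normal from the smoothed depth gradient gives the radial axis
    depth_smooth = ndi.gaussian_filter(edt_in, 3.0)
    grad_r, grad_c = np.gradient(depth_smooth)

    fa_mask = np.zeros((h, w), dtype=bool)
    centroids: list[tuple[float, float]] = []
    thetas: list[float] = []
    dilate = np.ones((5, 5), dtype=bool)
    for _ in range(config.n_fas):
        for attempt in range(1000):
            r, c = band_pixels[rng.integers(len(band_pixels))]
            jr, jc = rng.uniform(-0.5, 0.5, size=2)
            center = (float(r + jr), float(c + jc))
            # major axis along the radial (depth-gradient) direction
            theta_rc = math.atan2(grad_c[r, c], grad_r[r, c])
            cand = _half_max_ellipse(
                (h, w), center, theta_rc, config.fa_length_px, config.fa_width_px
            )
            if not cand.any():
                continue
            if not (ndi.binary_dilation(cand, structure=dilate) & fa_mask).any():
                fa_mask |= cand
                centroids.append(center)
                thetas.append(theta_rc)
                break
        else:
            raise ValueError("could not place non-overlapping FAs in 1000 attempts")
    return fa_mask, centroids, thetas


def _sample_cargo_centers(
    config: SimulationConfig,
    roi_mask: np.ndarray,
    fa_mask: np.ndarray | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Spot centers per cargo_mode plus their nearest-FA distances (µm)."""
    n = config.n_spots
    if n == 0:
        return np.empty((0, 2)), np.empty(0)
    if config.cargo_mode in ("fa_proximal", "on_fa") and (fa_mask is None or not fa_mask.any()):
        raise ValueError("no FAs to anchor cargo")

    if fa_mask is not None and fa_mask.any():
        edt_px = ndi.distance_transform_edt(~fa_mask)
    else:
        edt_px = np.full(roi_mask.shape, np.nan)

    if config.cargo_mode == "uniform":
        roi_pixels = np.argwhere(roi_mask)
        picks = roi_pixels[rng.integers(len(roi_pixels), size=n)]
        centers = picks.astype(float)
        dists = edt_px[picks[:, 0], picks[:, 1]] * config.pixel_size
        return centers, dists

    if config.cargo_mode == "on_fa":
        fa_pixels = np.argwhere(fa_mask)
        picks = fa_pixels[rng.integers(len(fa_pixels), size=n)]
        return picks.astype(float), np.zeros(n)

    # fa_proximal: sample a half-normal offset d (µm), then pick a ROI pixel
    # whose nearest-FA distance matches d to within half a pixel.
    d0_px = config.offset_scale_um / config.pixel_size
    roi_pixels = np.argwhere(roi_mask)
    roi_d = edt_px[roi_pixels[:, 0], roi_pixels[:, 1]]
    centers = np.empty((n, 2))
    dists = np.empty(n)
    for i in range(n):
        for _ in range(20):
            d = abs(rng.normal(0.0, d0_px))
            cand = np.flatnonzero(np.abs(roi_d - d) <= 0.5)
            if len(cand):
                break
        else:
            cand = np.flatnonzero(np.abs(roi_d - d) <= np.abs(roi_d - d).min() + 0.5)
        pick = roi_pixels[cand[rng.integers(len(cand))]]
        centers[i] = pick
        dists[i] = edt_px[pick[0], pick[1]] * config.pixel_size
    return centers, dists


def _render_with_noise(
    clean: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Poisson(signal + background) + Gaussian read noise camera model."""
    expected = np.clip(clean + config.background, 0.0, None)
    image = rng.poisson(expected).astype(float)
    if config.gaussian_read_noise_sd > 0:
        image += rng.normal(0.0, config.gaussian_read_noise_sd, size=image.shape)
    return image


def simulate_cell_scene(
    config: SimulationConfig,
) -> tuple[Image2D, Image2D, GroundTruth]:
    """Render a two-channel still scene (adhesions + cargo) with ground truth.

    The FA channel holds ``n_fas`` non-overlapping elongated blobs in a
    peripheral band of the ROI, oriented radially; the cargo channel holds
    ``n_spots`` PSF-shaped spots placed per ``cargo_mode``. The truth records
    the half-max FA mask, blob centroids, spot centers and each center's
    nearest-FA distance.
    """
    if config.n_fas == 0 and config.cargo_mode in ("fa_proximal", "on_fa"):
        raise ValueError("no FAs to anchor cargo")
    h, w = config.image_shape
    roi_mask = _roi_mask_from_spec(config.roi, (h, w))
    if not roi_mask.any():
        raise ValueError("empty ROI")

    fa_mask, centroids, thetas = _place_fas(config, roi_mask, _rng(config.seed, _STREAM_FA))

    fa_clean = np.zeros((h, w))
    sigma_u = config.fa_length_px / _FWHM
    sigma_v = config.fa_width_px / _FWHM
    for center, theta in zip(centroids, thetas):
        _add_anisotropic_gaussian(fa_clean, center, theta, sigma_u, sigma_v, config.amplitude)

    centers, dists = _sample_cargo_centers(
        config, roi_mask, fa_mask if config.n_fas else None, _rng(config.seed, _STREAM_CARGO)
    )
    cargo_clean = np.zeros((h, w))
    for center in centers:
        _add_spot(cargo_clean, center, config.spot_sigma_px, config.amplitude)

    fa_img = _render_with_noise(fa_clean, config, _rng(config.seed, _STREAM_NOISE_FA))
    cargo_img = _render_with_noise(cargo_clean, config, _rng(config.seed, _STREAM_NOISE_CARGO))

    truth = GroundTruth(
        fa_mask=fa_mask,
        fa_centroids=centroids,
        spot_centers=centers,
        spot_fa_distances_um=dists,
    )
    return (
        Image2D(fa_img, config.pixel_size, "fa"),
        Image2D(cargo_img, config.pixel_size, "cargo"),
        truth,
    )


def _point_along(path: np.ndarray, cum: np.ndarray, s: float) -> np.ndarray:
    """Point at arc length s along the polyline; clamps at the endpoint."""
    s = min(max(s, 0.0), cum[-1])
    i = int(np.searchsorted(cum, s, side="right")) - 1
    i = min(max(i, 0), len(path) - 2)
    seg_len = cum[i + 1] - cum[i]
    frac = 0.0 if seg_len == 0 else (s - cum[i]) / seg_len
    return path[i] + frac * (path[i + 1] - path[i])


def _random_polyline(
    rng: np.random.Generator,
    roi_mask: np.ndarray,
    shape: tuple[int, int],
    min_length_px: float,
) -> np.ndarray:
    """Gently turning polyline starting inside the cell, clipped to the frame."""
    h, w = shape
    depth = ndi.distance_transform_edt(roi_mask)
    interior = np.argwhere(depth >= min(5.0, max(depth.max() / 2.0, 1.0)))
    if len(interior) == 0:
        interior = np.argwhere(roi_mask)
    n_segments = 4
    seg_len = max(min_length_px, 4.0) * 1.5 / n_segments
    for _ in range(50):
        start = interior[rng.integers(len(interior))].astype(float)
        heading = rng.uniform(0.0, 2.0 * math.pi)
        pts = [start]
        for _ in range(n_segments):
            heading += rng.uniform(-0.6, 0.6)
            step = np.array([math.sin(heading), math.cos(heading)]) * seg_len
            nxt = np.clip(pts[-1] + step, [1.0, 1.0], [h - 2.0, w - 2.0])
            pts.append(nxt)
        path = np.asarray(pts)
        arc = float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum())
        if arc >= min_length_px:
            return path
    return path  # best effort; vesicles stop at the endpoint


def simulate_vesicle_movie(config: SimulationConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a movie of point emitters moving along polylines at set speed.

    With ``tracks_share_paths`` all vesicles reuse one polyline at staggered
    arc offsets; otherwise each gets its own. A vesicle reaching the end of
    its path stays at the endpoint. Truth holds exact per-frame positions
    and the programmed speed.
    """
    if config.n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    h, w = config.image_shape
    roi_mask = _roi_mask_from_spec(config.roi, (h, w))
    rng = _rng(config.seed, _STREAM_TRACKS)

    v_px_per_frame = config.speed_um_s * config.frame_interval_s / config.pixel_size
    travel_px = v_px_per_frame * (config.n_frames - 1)
    stagger_px = max(3.0 * config.spot_sigma_px, 3.0)
    n_paths = 1 if config.tracks_share_paths else config.n_vesicles
    need = travel_px + (config.n_vesicles * stagger_px if config.tracks_share_paths else 0.0)
    paths = [_random_polyline(rng, roi_mask, (h, w), need + 2.0) for _ in range(max(n_paths, 0))]

    tracks: list[np.ndarray] = []
    for k in range(config.n_vesicles):
        path = paths[0] if config.tracks_share_paths else paths[k]
        cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(path, axis=0), axis=1))])
        s0 = k * stagger_px if config.tracks_share_paths else 0.0
        positions = np.array(
            [_point_along(path, cum, s0 + v_px_per_frame * t) for t in range(config.n_frames)]
        )
        tracks.append(positions)

    noise_rng = _rng(config.seed, _STREAM_NOISE_MOVIE)
    frames = np.empty((config.n_frames, h, w))
    for t in range(config.n_frames):
        clean = np.zeros((h, w))
        for positions in tracks:
            _add_spot(clean, positions[t], config.spot_sigma_px, config.amplitude)
        frames[t] = _render_with_noise(clean, config, noise_rng)

    truth = GroundTruth(
        tracks=tracks,
        track_speeds_um_s=[config.speed_um_s] * config.n_vesicles,
    )
    stack = ImageStack(frames, config.pixel_size, config.frame_interval_s, "vesicles")
    return stack, truth
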