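import numpy as np
import pytest
from scipy import ndimage as ndi

import exoquant as eq
from exoquant import Image2D, count_objects, detect_spots, segment_objects
from exoquant.detection import normalized_spot_intensity, spot_density

from conftest import disk_image, gaussian_spot_image


def full_mask(shape):
    return np.ones(shape, dtype=bool)


class TestSegmentObjects:
    def test_all_zero_image(self):
        img = Image2D(np.zeros((32, 32)), 0.1)
        assert segment_objects(img, full_mask((32, 32)), sigma=1, threshold=10).n_objects == 0

    def test_two_disks(self):
        # component-count oracle: label the thresholded truth directly
        raw = disk_image((64, 64), [(16, 16), (48, 48)], radius=4, amplitude=100)
        img = Image2D(raw, 0.1)
        result = segment_objects(img, full_mask((64, 64)), sigma=1, threshold=50)
        _, n_oracle = ndi.label(raw > 50, structure=np.ones((3, 3)))
        assert n_oracle == 2
        assert result.n_objects == 2

    def test_threshold_above_max_gives_empty(self):
        raw = disk_image((32, 32), [(16, 16)], radius=4, amplitude=100)
        result = segment_objects(Image2D(raw, 0.1), full_mask((32, 32)), 1, 101)
        assert result.n_objects == 0
        assert not result.as_binary().any()

    def test_empty_roi_errors(self):
        img = Image2D(np.ones((8, 8)), 0.1)
        with pytest.raises(ValueError, match="empty ROI"):
            segment_objects(img, np.zeros((8, 8), dtype=bool), 1, 0.5)

    def test_otsu_computed_over_roi_only(self):
        # bright corner outside ROI must not influence the ROI threshold
        raw = np.zeros((32, 32))
        raw[:8, :8] = 1000.0
        raw[20:24, 20:24] = 10.0
        roi = np.zeros((32, 32), dtype=bool)
        roi[16:, 16:] = True
        result = segment_objects(Image2D(raw, 0.1), roi, sigma=0, threshold="otsu")
        assert result.threshold_used < 10.0
        assert result.n_objects == 1

    def test_provenance_recorded(self):
        raw = disk_image((32, 32), [(16, 16)])
        result = segment_objects(Image2D(raw, 0.1), full_mask((32, 32)), 2.0, 30.0)
        assert result.sigma_used == 2.0
        assert result.threshold_used == 30.0

    def test_monotone_in_threshold(self, rng):
        img = Image2D(rng.random((48, 48)) * 100, 0.1)
        mask = full_mask((48, 48))
        counts = [
            (segment_objects(img, mask, 1, thr).as_binary()).sum()
            for thr in (10, 30, 50, 70, 90)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_labels_respect_roi(self):
        raw = disk_image((32, 32), [(8, 8), (24, 24)], radius=3)
        roi = np.zeros((32, 32), dtype=bool)
        roi[:16, :16] = True
        result = segment_objects(Image2D(raw, 0.1), roi, 1, 50)
        assert result.n_objects == 1
        assert not (result.as_binary() & ~roi).any()


class TestDetectSpots:
    def test_constant_image(self):
        img = Image2D(np.full((32, 32), 7.0), 0.1)
        assert len(detect_spots(img, min_distance=3, prominence=1.0)) == 0

    def test_two_peaks_localized(self):
        img = Image2D(gaussian_spot_image((48, 48), [(10, 10), (30, 30)]), 0.1)
        spots = detect_spots(img, min_distance=5, prominence=20)
        assert len(spots) == 2
        pos = spots.positions()
        errors = [
            min(np.hypot(r - tr, c - tc) for r, c in pos) for tr, tc in [(10, 10), (30, 30)]
        ]
        assert max(errors) < 0.5

    def test_min_distance_conflict_keeps_brighter(self):
        raw = gaussian_spot_image((48, 48), [(30, 30)], amplitude=50) + gaussian_spot_image(
            (48, 48), [(10, 10)], amplitude=100
        )
        spots = detect_spots(Image2D(raw, 0.1), min_distance=40, prominence=10)
        assert len(spots) == 1
        assert np.hypot(spots.positions()[0, 0] - 10, spots.positions()[0, 1] - 10) < 0.5

    def test_equal_peaks_tie_breaks_to_lower_row_col(self):
        img = Image2D(gaussian_spot_image((48, 48), [(10, 10), (30, 30)]), 0.1)
        spots = detect_spots(img, min_distance=40, prominence=20)
        assert len(spots) == 1
        assert np.hypot(spots.positions()[0, 0] - 10, spots.positions()[0, 1] - 10) < 0.5

    def test_one_spot_per_peak_on_separated_grid(self):
        centers = [(r, c) for r in (10, 25, 40) for c in (10, 25, 40)]
        img = Image2D(gaussian_spot_image((50, 50), centers), 0.1)
        spots = detect_spots(img, min_distance=5, prominence=20)
        assert len(spots) == len(centers)
        for tr, tc in centers:
            err = min(np.hypot(r - tr, c - tc) for r, c in spots.positions())
            assert err < 0.5

    def test_contract_validation(self):
        img = Image2D(np.zeros((8, 8)), 0.1)
        with pytest.raises(ValueError):
            detect_spots(img, min_distance=0, prominence=1)
        with pytest.raises(ValueError):
            detect_spots(img, min_distance=3, prominence=0)


class TestCountObjects:
    def test_min_area_filter(self):
        labels = np.zeros((32, 32), dtype=int)
        labels[0, :3] = 1  # area 3
        labels[10:15, 10:20] = 2  # area 50
        mask = eq.LabelMask(labels, 2, 1.0, 10.0)
        assert count_objects(mask, min_area=10) == 1

    def test_min_area_zero_is_identity(self):
        labels = np.zeros((16, 16), dtype=int)
        labels[2, 2] = 1
        labels[8:10, 8:10] = 2
        mask = eq.LabelMask(labels, 2, 1.0, 10.0)
        assert count_objects(mask, 0) == mask.n_objects

    def test_random_blobs_match_pixel_histogram_oracle(self, rng):
        raw = (rng.random((128, 128)) < 0.05).astype(float) * 100
        raw = ndi.grey_dilation(raw, size=3)
        result = segment_objects(Image2D(raw, 0.1), full_mask((128, 128)), 0, 50)
        areas = np.bincount(result.labels.ravel())[1:]
        median = float(np.median(areas))
        oracle = int((areas >= median).sum())
        assert count_objects(result, min_area=median) == oracle


class TestSpotDensity:
    def test_ratio(self):
        table = {"frame": [0] * 10, "row": np.linspace(5, 50, 10), "col": np.linspace(5, 50, 10),
                 "peak": [1.0] * 10, "mean": [1.0] * 10, "area": [25] * 10}
        import pandas as pd

        spots = eq.SpotSet(pd.DataFrame(table))
        roi = np.zeros((100, 100), dtype=bool)
        roi[:100, :100] = True
        # 10,000 px at 0.1 um/px -> 100 um^2
        per_cell, per_area = spot_density(spots, roi, pixel_size=0.1)
        assert per_cell == 10
        assert per_area == pytest.approx(0.1)

    def test_empty_spotset(self):
        roi = np.ones((10, 10), dtype=bool)
        assert spot_density(eq.SpotSet(), roi, 0.1) == (0, 0.0)

    def test_empty_roi_errors(self):
        with pytest.raises(ValueError, match="empty ROI"):
            spot_density(eq.SpotSet(), np.zeros((5, 5), dtype=bool), 0.1)

    def test_ground_truth_recovery(self):
        config = eq.SimulationConfig(
            image_shape=(200, 200), seed=21, n_fas=6, n_spots=40,
            cargo_mode="uniform", amplitude=500.0, background=5.0,
            gaussian_read_noise_sd=1.0, n_vesicles=0,
        )
        _, cargo, truth = eq.simulate_cell_scene(config)
        from exoquant.synthetic import _roi_mask_from_spec

        roi = _roi_mask_from_spec(config.roi, config.image_shape)
        spots = detect_spots(cargo, roi, min_distance=3, prominence=50)
        per_cell, _ = spot_density(spots, roi, config.pixel_size)
        # spots may overlap by chance; all detections must be genuine
        assert per_cell <= 40
        assert per_cell >= 35


class TestNormalizedSpotIntensity:
    def test_uniform_image_gives_one(self):
        img = Image2D(np.full((16, 16), 5.0), 0.1)
        spot = np.zeros((16, 16), dtype=bool)
        spot[4:6, 4:6] = True
        assert normalized_spot_intensity(img, spot, full_mask((16, 16))) == pytest.approx(1.0)

    def test_constructed_ratio(self):
        # build arrays with spot-pixel mean 50 and overall ROI mean 10 -> 5.0
        spot = np.zeros((10, 10), dtype=bool)
        spot[0, :2] = True
        raw = np.full((10, 10), (10.0 * 100 - 50.0 * 2) / 98)
        raw[spot] = 50.0
        roi = full_mask((10, 10))
        assert normalized_spot_intensity(Image2D(raw, 0.1), spot, roi) == pytest.approx(5.0)

    def test_identity_mask_gives_one(self, rng):
        raw = rng.random((20, 20)) + 0.1
        roi = full_mask((20, 20))
        assert normalized_spot_intensity(Image2D(raw, 0.1), roi, roi) == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        raw = rng.random((20, 20)) + 0.1
        spot = np.zeros((20, 20), dtype=bool)
        spot[3:7, 3:7] = True
        roi = full_mask((20, 20))
        base = normalized_spot_intensity(Image2D(raw, 0.1), spot, roi)
        scaled = normalized_spot_intensity(Image2D(raw * 37.5, 0.1), spot, roi)
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_empty_spot_mask_errors(self):
        img = Image2D(np.ones((8, 8)), 0.1)
        with pytest.raises(ValueError, match="no secreted spots"):
            normalized_spot_intensity(img, np.zeros((8, 8), dtype=bool), full_mask((8, 8)))

    def test_spot_outside_roi_errors(self):
        img = Image2D(np.ones((8, 8)), 0.1)
        spot = np.zeros((8, 8), dtype=bool)
        spot[0, 0] = True
        roi = np.zeros((8, 8), dtype=bool)
        roi[4:, 4:] = True
        with pytest.raises(ValueError):
            normalized_spot_intensity(img, spot, roi)
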