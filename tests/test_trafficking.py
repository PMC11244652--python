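"""Thresholding, counting, retention and infiltration-distance quantification."""

import numpy as np
import pytest
from scipy import ndimage

from dermaflux import trafficking as tq

PX = 5.0  # um/px used throughout


def disk_frame(shape, centers_rc, radius=3, value=200.0):
    frame = np.zeros(shape)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for r, c in centers_rc:
        frame[(yy - r) ** 2 + (xx - c) ** 2 <= radius**2] = value
    return frame


def grid_centers(n, shape, spacing=12, offset=6):
    per_row = (shape[1] - offset) // spacing
    return [
        (offset + spacing * (i // per_row), offset + spacing * (i % per_row))
        for i in range(n)
    ]


class TestBinarize:
    def test_zero_frame_fixed_threshold_empty_mask(self):
        mask = tq.binarize(np.zeros((32, 32)), method="fixed", threshold=1)
        assert not mask.any()

    def test_otsu_recovers_disk_area_on_synthetic_frame(self):
        shape = (128, 128)
        centers = grid_centers(50, shape)
        frame = disk_frame(shape, centers) + 5.0  # dim background pedestal
        mask, thr = tq.binarize(frame, return_threshold=True)
        true_area = (disk_frame(shape, centers) > 0).sum()
        assert mask.sum() == pytest.approx(true_area, rel=0.05)
        assert 0 <= thr < 255

    def test_constant_frame_otsu_suggests_fixed(self):
        with pytest.raises(tq.QuantError, match="fixed"):
            tq.binarize(np.full((16, 16), 7.0))

    def test_intensity_inversion_yields_complementary_mask(self):
        rng = np.random.default_rng(0)
        frame = rng.integers(0, 256, (64, 64)).astype(float)
        frame[0, 0], frame[0, 1] = 0.0, 255.0  # pin the 8-bit range
        thr = 100
        mask = tq.binarize(frame, method="fixed", threshold=thr)
        # img <= t  <=>  255 - img > 255 - t - 1  (integer intensities)
        inv_mask = tq.binarize(255.0 - frame, method="fixed", threshold=255 - thr - 1)
        assert np.array_equal(inv_mask, ~mask)


class TestDetectCells:
    def test_empty_mask_zero_detections(self):
        det = tq.detect_cells(np.zeros((32, 32), dtype=bool), PX)
        assert det.count == 0

    def test_fifty_disks_counted_with_accurate_centroids(self):
        shape = (128, 128)
        centers = grid_centers(50, shape)
        mask = disk_frame(shape, centers) > 0
        det = tq.detect_cells(mask, PX)
        assert det.count == 50
        got = np.sort(det.centroids_um.view("f8,f8"), order=["f1", "f0"], axis=0)
        expected = np.sort(
            np.array([((c + 0.5) * PX, (r + 0.5) * PX) for r, c in centers])
            .view("f8,f8"), order=["f1", "f0"], axis=0
        )
        diffs = np.abs(got.view(float).reshape(-1, 2) - expected.view(float).reshape(-1, 2))
        assert diffs.max() <= PX  # within one pixel

    def test_min_area_filter_drops_small_component(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[5, 5] = True  # single pixel: 25 um^2 < default 100 um^2
        assert tq.detect_cells(mask, PX).count == 0


class TestRetention:
    def make_stack(self, frame_list):
        return tq.ImageStack(
            frames=np.array(frame_list),
            timestamps_s=np.arange(len(frame_list)) * 300.0,
            pixel_size_um=PX,
        )

    def test_identical_frames_hold_100pct(self):
        frame = disk_frame((64, 64), grid_centers(10, (64, 64)))
        stack = self.make_stack([frame, frame, frame])
        roi = tq.RegionOfInterest.rectangle("dev", 0, 0, 64 * PX, 64 * PX)
        res = tq.retention_timeseries(stack, roi)
        assert np.allclose(res.retention_pct, 100.0)

    def test_dropped_cells_lower_retention(self):
        centers = grid_centers(20, (64, 64))
        stack = self.make_stack(
            [disk_frame((64, 64), centers), disk_frame((64, 64), centers[:9])]
        )
        roi = tq.RegionOfInterest.rectangle("dev", 0, 0, 64 * PX, 64 * PX)
        res = tq.retention_timeseries(stack, roi)
        assert res.counts.tolist() == [20, 9]
        assert res.retention_pct[1] == pytest.approx(45.0)

    def test_empty_baseline_roi_is_an_error(self):
        frame = disk_frame((64, 64), [(40, 40)])
        stack = self.make_stack([frame, frame])
        roi = tq.RegionOfInterest.rectangle("corner", 0, 0, 10 * PX, 10 * PX)
        with pytest.raises(tq.QuantError, match="baseline"):
            tq.retention_timeseries(stack, roi)

    def test_single_zone_covering_all_equals_whole_device(self):
        centers = grid_centers(15, (64, 64))
        stack = self.make_stack(
            [disk_frame((64, 64), centers), disk_frame((64, 64), centers[:7])]
        )
        whole = tq.RegionOfInterest.rectangle("dev", 0, 0, 64 * PX, 64 * PX)
        per_zone = tq.zone_retention(stack, [whole])
        ref = tq.retention_timeseries(stack, whole)
        assert np.array_equal(per_zone["dev"].retention_pct, ref.retention_pct)

    def test_overlapping_zones_rejected(self):
        frame = disk_frame((64, 64), grid_centers(5, (64, 64)))
        stack = self.make_stack([frame])
        a = tq.RegionOfInterest.rectangle("a", 0, 0, 200, 200)
        b = tq.RegionOfInterest.rectangle("b", 100, 100, 300, 300)
        with pytest.raises(tq.QuantError, match="overlap"):
            tq.zone_retention(stack, [a, b])

    def test_zone_without_baseline_cells_reported_undefined(self):
        frame = disk_frame((64, 64), [(10, 10)])
        stack = self.make_stack([frame, frame])
        occupied = tq.RegionOfInterest.rectangle("left", 0, 0, 160, 160)
        empty = tq.RegionOfInterest.rectangle("right", 200, 200, 300, 300)
        res = tq.zone_retention(stack, [occupied, empty])
        assert res["right"] is None
        assert np.allclose(res["left"].retention_pct, 100.0)


class TestRelativeDecrease:
    @pytest.mark.parametrize(
        "early, late, expected",
        [(60.0, 45.0, 25.0), (55.0, 20.0, 63.6), (42.0, 42.0, 0.0)],
    )
    def test_values(self, early, late, expected):
        assert tq.relative_decrease(early, late) == pytest.approx(expected, abs=0.05)

    def test_nonpositive_early_rejected(self):
        with pytest.raises(tq.QuantError):
            tq.relative_decrease(0.0, 10.0)


class TestInfiltration:
    def straight_vessel(self, shape=(128, 128), cols=10):
        vessel = np.zeros(shape, dtype=bool)
        vessel[:, :cols] = True
        return vessel

    def test_centroid_on_vessel_boundary_scores_zero(self):
        vessel = self.straight_vessel()
        dist = tq.nearest_vessel_distance_map(vessel, PX)
        assert dist[64, 9] == 0.0   # last vessel column
        assert dist[64, 10] == PX   # first gel column

    def test_constructed_distances_recovered_within_one_pixel(self):
        vessel = self.straight_vessel()
        # cells at 100, 200, 300 um from the vessel edge (last vessel pixel)
        centers = [(30, 9 + 20), (64, 9 + 40), (100, 9 + 60)]
        cells = disk_frame(vessel.shape, centers) > 0
        res = tq.infiltration_analysis(cells, vessel, PX)
        assert res.count == 3
        assert np.allclose(np.sort(res.distances_um), [100.0, 200.0, 300.0], atol=PX)
        assert res.mean_um <= res.max_um

    def test_cells_inside_lumen_excluded(self):
        vessel = self.straight_vessel()
        cells = disk_frame(vessel.shape, [(64, 4)]) > 0
        res = tq.infiltration_analysis(cells, vessel, PX)
        assert res.count == 0
        assert res.excluded_in_lumen == 1

    def test_empty_vessel_mask_rejected(self):
        with pytest.raises(tq.QuantError):
            tq.infiltration_analysis(
                np.zeros((16, 16), dtype=bool), np.zeros((16, 16), dtype=bool), PX
            )

    def test_distance_map_matches_brute_force_on_small_image(self):
        rng = np.random.default_rng(42)
        vessel = rng.random((48, 48)) < 0.05
        vessel[0, 0] = True
        dist = tq.nearest_vessel_distance_map(vessel, PX)
        rr, cc = np.nonzero(vessel)
        yy, xx = np.mgrid[:48, :48]
        brute = np.min(
            np.sqrt((yy[..., None] - rr) ** 2 + (xx[..., None] - cc) ** 2), axis=-1
        ) * PX
        assert np.abs(dist - brute).max() <= PX * np.sqrt(2.0)

    def test_determinism(self):
        vessel = self.straight_vessel()
        cells = disk_frame(vessel.shape, [(30, 40), (80, 90)]) > 0
        a = tq.infiltration_analysis(cells, vessel, PX)
        b = tq.infiltration_analysis(cells, vessel, PX)
        assert np.array_equal(a.distances_um, b.distances_um)
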