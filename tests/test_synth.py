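"""Synthetic generators: determinism, recorded truth, and round-trip recovery."""

import numpy as np
import pytest

from dermaflux import synth
from dermaflux import trafficking as tq
from dermaflux import transport as tr

PX = synth.CELL_PIXEL_SIZE_UM


@pytest.fixture(scope="module")
def small_strip():
    return tr.strip_domain(length_um=600.0, spacing_um=20.0, rows=8)


class TestDextranTimelapse:
    def test_sealed_barrier_gel_stays_dark(self, small_strip):
        stacks, truth = synth.gen_dextran_timelapse(
            small_strip,
            dyes={"dye": {"d_um2_s": 16.0, "p_um_s": 0.0}},
            noise_sd=0.0, duration_s=900.0, frame_interval_s=300.0,
        )
        gel = small_strip.gel_mask
        assert np.all(stacks["dye"].frames[:, gel] == 0.0)

    def test_same_seed_bit_identical(self, small_strip):
        kwargs = dict(duration_s=600.0, frame_interval_s=300.0, seed=7)
        a, _ = synth.gen_dextran_timelapse(small_strip, **kwargs)
        b, _ = synth.gen_dextran_timelapse(small_strip, **kwargs)
        for dye in a:
            assert np.array_equal(a[dye].frames, b[dye].frames)

    def test_truth_records_study_transport_parameters(self, small_strip):
        _, truth = synth.gen_dextran_timelapse(
            small_strip, duration_s=600.0, frame_interval_s=300.0, seed=1
        )
        dyes = truth.transport["dyes"]
        assert dyes["dex20kda"] == {"d_um2_s": 16.0, "p_um_s": 0.62}
        assert dyes["dex40kda"] == {"d_um2_s": 53.0, "p_um_s": 0.41}
        assert truth.seed == 1

    def test_noise_perturbs_but_preserves_mean(self, small_strip):
        noisy, _ = synth.gen_dextran_timelapse(
            small_strip, dyes={"dye": {"d_um2_s": 16.0, "p_um_s": 5.0}},
            noise_sd=0.05, duration_s=900.0, frame_interval_s=300.0, seed=3,
        )
        clean, _ = synth.gen_dextran_timelapse(
            small_strip, dyes={"dye": {"d_um2_s": 16.0, "p_um_s": 5.0}},
            noise_sd=0.0, duration_s=900.0, frame_interval_s=300.0, seed=3,
        )
        nf, cf = noisy["dye"].frames[-1], clean["dye"].frames[-1]
        assert not np.array_equal(nf, cf)
        bright = cf > 0.2
        rel = nf[bright] / cf[bright]
        assert np.mean(rel) == pytest.approx(1.0, abs=0.01)
        assert np.std(rel) == pytest.approx(0.05, abs=0.01)


class TestTcellPerfusion:
    ZONES = [
        tq.RegionOfInterest.rectangle("A", 0.0, 0.0, 400.0, 400.0),
        tq.RegionOfInterest.rectangle("B", 420.0, 0.0, 820.0, 400.0),
    ]

    def vessel(self):
        mask = np.zeros((80, 164), dtype=bool)  # 400 x 820 um at 5 um/px
        mask[20:60, :] = True
        return mask

    def test_survival_one_keeps_counts_constant(self):
        stack, truth = synth.gen_tcell_perfusion(
            self.vessel(), PX, self.ZONES,
            attach_counts={"A": 12, "B": 12},
            survival={"A": [1.0, 1.0], "B": [1.0, 1.0]}, seed=0,
        )
        counts = truth.trafficking["per_frame_counts"]
        assert all(c == {"A": 12, "B": 12} for c in counts)

    def test_same_seed_identical_stacks(self):
        kwargs = dict(
            attach_counts={"A": 10, "B": 10},
            survival={"A": [0.5, 0.5], "B": [0.9, 0.9]}, seed=11,
        )
        a, _ = synth.gen_tcell_perfusion(self.vessel(), PX, self.ZONES, **kwargs)
        b, _ = synth.gen_tcell_perfusion(self.vessel(), PX, self.ZONES, **kwargs)
        assert np.array_equal(a.frames, b.frames)

    def test_requesting_more_cells_than_vessel_pixels_errors(self):
        with pytest.raises(synth.SynthError, match="vessel pixels"):
            synth.gen_tcell_perfusion(
                self.vessel(), PX, self.ZONES,
                attach_counts={"A": 10_000, "B": 1},
                survival={"A": [1.0], "B": [1.0]},
                frame_times_s=(0.0, 300.0), seed=0,
            )

    def test_whole_device_counts_track_cumulative_survival(self):
        # cumulative 55% / 20% of baseline: counts over many seeds average there
        per_interval = synth.interval_survival_from_cumulative(synth.NAIVE_SURVIVAL)
        assert per_interval[0] == pytest.approx(0.55)
        assert per_interval[1] == pytest.approx(0.20 / 0.55)
        n0, ratios_5, ratios_10 = 24, [], []
        for seed in range(30):
            _, truth = synth.gen_tcell_perfusion(
                self.vessel(), PX, self.ZONES,
                attach_counts={"A": n0, "B": n0},
                survival={"A": per_interval, "B": per_interval}, seed=seed,
            )
            counts = truth.trafficking["per_frame_counts"]
            total0 = sum(counts[0].values())
            ratios_5.append(sum(counts[1].values()) / total0)
            ratios_10.append(sum(counts[2].values()) / total0)
        n_total = 30 * 2 * n0
        for mean, p in ((np.mean(ratios_5), 0.55), (np.mean(ratios_10), 0.20)):
            se = np.sqrt(p * (1 - p) / n_total)
            assert abs(mean - p) < 3 * se

    def test_roundtrip_counts_recovered_exactly(self):
        stack, truth = synth.gen_tcell_perfusion(
            self.vessel(), PX, self.ZONES,
            attach_counts={"A": 15, "B": 15},
            survival={"A": [0.6, 0.4], "B": [0.8, 0.7]}, seed=5,
        )
        res = tq.zone_retention(stack, self.ZONES)
        for z in ("A", "B"):
            assert res[z].counts.tolist() == [
                c[z] for c in truth.trafficking["per_frame_counts"]
            ]


class TestInfiltrationEndpoint:
    def vessel(self):
        mask = np.zeros((160, 160), dtype=bool)  # 800 x 800 um at 5 um/px
        mask[:, :12] = True
        return mask

    def test_zero_cells_blank_image(self):
        img, truth = synth.gen_infiltration_endpoint(
            self.vessel(), PX, n_cells=0,
            distance_model={"kind": "half_normal", "mean_um": 100.0}, seed=0,
        )
        assert not img.any()
        assert truth.infiltration["placed_distances_um"] == []

    def test_fixed_distances_pass_through_to_truth(self):
        _, truth = synth.gen_infiltration_endpoint(
            self.vessel(), PX,
            distance_model={"kind": "fixed", "distances_um": [100.0, 200.0]}, seed=0,
        )
        assert truth.infiltration["sampled_distances_um"] == [100.0, 200.0]
        placed = truth.infiltration["placed_distances_um"]
        assert np.allclose(sorted(placed), [100.0, 200.0], atol=PX)

    def test_roundtrip_distances_within_one_pixel(self):
        img, truth = synth.gen_infiltration_endpoint(
            self.vessel(), PX,
            distance_model={"kind": "fixed",
                            "distances_um": [60.0, 150.0, 300.0, 450.0]},
            seed=2,
        )
        res = tq.infiltration_analysis(tq.binarize(img), self.vessel(), PX)
        assert res.count == 4
        assert np.allclose(
            np.sort(res.distances_um),
            np.sort(truth.infiltration["placed_distances_um"]),
            atol=PX,
        )

    def test_oversized_distance_rejected(self):
        with pytest.raises(synth.SynthError, match="extent"):
            synth.gen_infiltration_endpoint(
                self.vessel(), PX,
                distance_model={"kind": "fixed", "distances_um": [5000.0]}, seed=0,
            )

    def test_epidermis_raises_mean_migration_distance(self):
        # with-epidermis (mean 233 um, n=22) vs without (mean 68 um, n=15)
        vessel = np.zeros((240, 240), dtype=bool)  # 1.2 x 1.2 mm at 5 um/px
        vessel[:, :12] = True
        wins = 0
        for seed in range(100):
            _, with_epi = synth.gen_infiltration_endpoint(
                vessel, PX, distance_model="with_epidermis", seed=seed)
            _, without = synth.gen_infiltration_endpoint(
                vessel, PX, distance_model="without_epidermis", seed=seed + 10_000)
            wins += (
                np.mean(with_epi.infiltration["placed_distances_um"])
                > np.mean(without.infiltration["placed_distances_um"])
            )
        assert wins >= 95
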