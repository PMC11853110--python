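"""Preprocessing: anomaly repair, ROI segmentation, cycles, average maps."""

import numpy as np
import pytest

from gaitpress import preprocess as pp
from gaitpress import simulate as sim


def make_seq(frames, **kw):
    return sim.PressureFrameSequence(
        frames=np.asarray(frames, dtype=np.uint8), subject_id=0, **kw)


class TestReplaceAnomalies:
    def test_all_zero_sequence_unchanged(self):
        seq = make_seq(np.zeros((3, 192, 40)))
        out = pp.replace_anomalies(seq)
        assert not out.frames.any()

    def test_single_spike_becomes_neighbour_mean(self):
        f = np.zeros((1, 192, 40))
        f[0, 10:13, 10:13] = 10
        f[0, 11, 11] = 255
        out = pp.replace_anomalies(make_seq(f), z_threshold=4.0)
        assert out.frames[0, 11, 11] == 10
        # the ring of neighbours is untouched
        assert (out.frames[0, 10:13, 10:13].sum()
                == 9 * 10)

    def test_isolated_spike_on_empty_mat_removed(self):
        f = np.zeros((2, 192, 40))
        f[1, 50, 20] = 255
        out = pp.replace_anomalies(make_seq(f))
        assert not out.frames.any()

    def test_smooth_footprint_untouched(self, quiet_walk):
        out = pp.replace_anomalies(quiet_walk, z_threshold=4.0)
        np.testing.assert_array_equal(out.frames, quiet_walk.frames)

    def test_injected_anomalies_are_removed(self, small_cohort):
        p = small_cohort[0]
        clean = sim.simulate_walk(p, sim.WalkCondition(), 6,
                                  noise_sd=0, anomaly_rate=0, seed=9)
        spiky = sim.simulate_walk(p, sim.WalkCondition(), 6,
                                  noise_sd=0, anomaly_rate=0.3, seed=9)
        repaired = pp.replace_anomalies(spiky)
        # residual difference from the clean walk is tiny relative to spikes
        before = np.abs(spiky.frames.astype(int) - clean.frames.astype(int))
        after = np.abs(repaired.frames.astype(int) - clean.frames.astype(int))
        assert before.max() >= 200
        assert after.max() <= 30
        assert after.sum() < 0.05 * before.sum()


class TestAccumulate:
    def test_sum_of_identical_constant_frames(self):
        f = np.full((5, 192, 40), 7)
        assert (pp.accumulate_pressure(make_seq(f)) == 35).all()

    def test_single_frame_identity(self, quiet_walk):
        one = make_seq(quiet_walk.frames[:1])
        np.testing.assert_array_equal(pp.accumulate_pressure(one),
                                      quiet_walk.frames[0].astype(np.int64))

    def test_matches_explicit_loop(self):
        rng = np.random.default_rng(4)
        f = rng.integers(0, 255, size=(3, 192, 40), dtype=np.uint8)
        expected = np.zeros((192, 40), dtype=np.int64)
        for t in range(3):
            expected += f[t]
        np.testing.assert_array_equal(pp.accumulate_pressure(make_seq(f)),
                                      expected)

    def test_no_8bit_clipping_in_the_sum(self):
        f = np.full((10, 192, 40), 200)
        assert pp.accumulate_pressure(make_seq(f)).max() == 2000

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pp.accumulate_pressure(make_seq(np.zeros((0, 192, 40))))


class TestRois:
    def test_empty_mat_gives_no_rois(self):
        seq = make_seq(np.zeros((2, 192, 40)))
        assert pp.extract_rois(pp.accumulate_pressure(seq), seq) == []

    def test_windows_are_32_by_16(self, quiet_walk):
        rois = pp.extract_rois(pp.accumulate_pressure(quiet_walk), quiet_walk)
        assert pp.ROI_ROWS == 32 and pp.ROI_COLS == 16
        for r in rois:
            ys, xs = r.coords_y, r.coords_x
            assert (ys >= r.row0).all() and (ys < r.row0 + 32).all()
            assert (xs >= r.col0).all() and (xs < r.col0 + 16).all()

    def test_four_step_walk_onsets_increase_sides_alternate(self, quiet_walk):
        rois = pp.extract_rois(pp.accumulate_pressure(quiet_walk), quiet_walk)
        assert len(rois) == 4
        onsets = [r.onset_frame for r in rois]
        assert onsets == sorted(onsets) and len(set(onsets)) == 4
        assert [r.side for r in rois] == ["left", "right", "left", "right"]

    def test_correlation_localization_agrees_with_component(self, quiet_walk):
        summed = pp.accumulate_pressure(quiet_walk)
        a = pp.extract_rois(summed, quiet_walk, localization="component")
        b = pp.extract_rois(summed, quiet_walk, localization="correlation")
        for ra, rb in zip(a, b):
            assert abs(ra.row0 - rb.row0) <= 2
            assert abs(ra.col0 - rb.col0) <= 2

    def test_oversized_footprint_rejected(self):
        f = np.zeros((1, 192, 40))
        f[0, 10:60, 5:15] = 50  # 50-row blob
        seq = make_seq(f)
        with pytest.raises(ValueError, match="exceeds"):
            pp.extract_rois(pp.accumulate_pressure(seq), seq)

    def test_min_mass_filters_specks(self):
        f = np.zeros((1, 192, 40))
        f[0, 100, 30] = 3
        seq = make_seq(f)
        assert pp.extract_rois(pp.accumulate_pressure(seq), seq,
                               min_mass=50) == []


class TestCycles:
    @staticmethod
    def _rois_from(seq):
        return pp.extract_rois(pp.accumulate_pressure(seq), seq)

    @pytest.mark.parametrize("n_steps,expected", [(1, 0), (3, 2), (4, 3)])
    def test_n_steps_give_n_minus_1_cycles(self, small_cohort, n_steps,
                                           expected):
        seq = sim.simulate_walk(small_cohort[1], sim.WalkCondition(), n_steps,
                                noise_sd=0, anomaly_rate=0, seed=3)
        assert len(pp.detect_gait_cycles(self._rois_from(seq))) == expected

    def test_cycle_spans_two_step_onsets(self, quiet_walk):
        rois = self._rois_from(quiet_walk)
        cycles = pp.detect_gait_cycles(rois)
        for i, c in enumerate(cycles[:-1]):
            assert c.start_frame == rois[i].onset_frame
            assert c.end_frame == rois[i + 2].onset_frame
            assert c.duration_frames >= 1
        assert cycles[-1].end_frame == rois[-1].offset_frame + 1

    def test_unsorted_rois_rejected(self, quiet_walk):
        rois = self._rois_from(quiet_walk)
        with pytest.raises(ValueError, match="sorted"):
            pp.detect_gait_cycles(rois[::-1])


class TestAverageMap:
    def test_constant_pressure_maps_to_itself(self):
        f = np.zeros((4, 192, 40))
        f[:, 50:60, 5:10] = 12
        seq = make_seq(f)
        roi = pp.FootprintROI(row0=40, col0=0, side="left", onset_frame=0,
                              offset_frame=3, coords_x=np.arange(5) + 5,
                              coords_y=np.arange(10) + 50)
        cyc = pp.GaitCycle(index=1, start_frame=0, end_frame=4, rois=(roi,))
        m = pp.compute_average_map(seq, cyc)
        assert m.grid.shape == (32, 32)
        assert m.grid[10:20, 5:10] == pytest.approx(12)

    def test_two_frame_cycle_averages_values(self):
        f = np.zeros((2, 192, 40))
        f[0, 50, 5] = 4
        f[1, 50, 5] = 6
        seq = make_seq(f)
        roi = pp.FootprintROI(row0=40, col0=0, side="left", onset_frame=0,
                              offset_frame=1, coords_x=np.array([5]),
                              coords_y=np.array([50]))
        cyc = pp.GaitCycle(index=1, start_frame=0, end_frame=2, rois=(roi,))
        assert pp.compute_average_map(seq, cyc).grid[10, 5] == pytest.approx(5)

    def test_mass_conservation(self, quiet_walk):
        rois = pp.extract_rois(pp.accumulate_pressure(quiet_walk), quiet_walk)
        for cyc in pp.detect_gait_cycles(rois):
            m = pp.compute_average_map(quiet_walk, cyc)
            window = quiet_walk.frames[cyc.start_frame:cyc.end_frame].astype(
                np.float64)
            for roi in cyc.rois:
                half = slice(0, 16) if roi.side == "left" else slice(16, 32)
                expected = window[:, roi.row0:roi.row0 + 32,
                                  roi.col0:roi.col0 + 16].sum(axis=0)
                np.testing.assert_allclose(
                    m.grid[:, half] * cyc.duration_frames, expected,
                    rtol=1e-5, atol=1e-3)

    def test_count_law_n_minus_1(self, small_cohort):
        for n in range(2, 11):
            seq = sim.simulate_walk(small_cohort[3], sim.WalkCondition(), n,
                                    noise_sd=0, anomaly_rate=0, seed=n)
            assert len(pp.maps_from_sequence(seq, z_threshold=None)) == n - 1

    def test_mirrored_sequence_yields_flipped_maps(self, quiet_walk):
        mirrored = sim.PressureFrameSequence(
            frames=quiet_walk.frames[:, :, ::-1].copy(),
            subject_id=quiet_walk.subject_id)
        a = pp.maps_from_sequence(quiet_walk, z_threshold=None)
        b = pp.maps_from_sequence(mirrored, z_threshold=None)
        assert len(a) == len(b)
        for ma, mb in zip(a, b):
            np.testing.assert_allclose(mb.grid, np.fliplr(ma.grid), atol=1e-5)


class TestAugmentAndPartition:
    def test_flip_is_an_involution(self, quiet_walk):
        maps = pp.maps_from_sequence(quiet_walk, z_threshold=None)
        flipped_once = pp.augment_flip(maps)[len(maps):]
        flipped_twice = pp.augment_flip(flipped_once)[len(maps):]
        for m0, m2 in zip(maps, flipped_twice):
            np.testing.assert_array_equal(m0.grid, m2.grid)

    def test_flip_moves_hot_column(self):
        g = np.zeros((32, 32))
        g[:, 3] = 1.0
        m = pp.AveragePressureMap(grid=g, subject_id=0, condition="type_i",
                                  cycle_index=1)
        flipped = pp.augment_flip([m])[1]
        assert flipped.augmented
        assert flipped.grid[:, 31 - 3].sum() == pytest.approx(32)
        assert flipped.grid[:, 3].sum() == 0

    def test_output_count_doubles(self, quiet_walk):
        maps = pp.maps_from_sequence(quiet_walk, z_threshold=None)
        assert len(pp.augment_flip(maps)) == 2 * len(maps)

    @staticmethod
    def _toy_maps(n_subjects=4, rounds=(1, 2, 3, 4), per_round=5):
        maps = []
        for sid in range(n_subjects):
            for rid in rounds:
                cond = "type_i" if rid <= 3 else "type_ii"
                for ci in range(per_round):
                    maps.append(pp.AveragePressureMap(
                        grid=np.zeros((32, 32)), subject_id=sid,
                        condition=cond, cycle_index=ci + 1, round_id=rid))
        return maps

    def test_closed_set_partition_counts(self):
        maps = self._toy_maps()
        parts = pp.build_datasets(maps, pp.PartitionSpec.closed_set(
            augment=False))
        assert len(parts["train"]) == 4 * 2 * 5
        assert len(parts["test_type_i"]) == 4 * 1 * 5
        assert len(parts["test_type_ii"]) == 4 * 1 * 5

    def test_open_set_partition_counts(self):
        maps = self._toy_maps()
        parts = pp.build_datasets(
            maps, pp.PartitionSpec.open_set([0, 1, 2], augment=False))
        assert len(parts["train"]) == 3 * 2 * 5
        total = sum(map(len, parts.values()))
        assert total == len(maps)

    def test_partition_disjointness(self):
        maps = self._toy_maps()
        parts = pp.build_datasets(maps, pp.PartitionSpec.closed_set())
        train_keys = {(m.subject_id, m.round_id, m.trial_id, m.cycle_index)
                      for m in parts["train"]}
        test_keys = {(m.subject_id, m.round_id, m.trial_id, m.cycle_index)
                     for m in parts["test_type_i"] + parts["test_type_ii"]}
        assert not train_keys & test_keys

    def test_augmentation_applies_to_training_only(self):
        maps = self._toy_maps()
        parts = pp.build_datasets(maps, pp.PartitionSpec.closed_set())
        assert sum(m.augmented for m in parts["train"]) == len(parts["train"]) // 2
        assert not any(m.augmented for m in parts["test_type_i"])

    def test_map_io_roundtrip(self, tmp_path, quiet_walk):
        maps = pp.maps_from_sequence(quiet_walk, z_threshold=None)
        pp.save_maps(maps, tmp_path)
        loaded = pp.load_maps(tmp_path)
        assert len(loaded) == len(maps)
        for a, b in zip(maps, loaded):
            np.testing.assert_allclose(a.grid, b.grid, atol=1e-6)
            assert a.subject_id == b.subject_id
            assert a.cycle_index == b.cycle_index
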