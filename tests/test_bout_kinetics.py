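import numpy as np
import pytest

from conftest import mean_sem
from oracles import brute_force_bouts, brute_force_labels, random_track_arrays
from nfkin.bout_kinetics import (classify_direction, label_intervals,
                                 qualify_track, segment_bouts)
from nfkin.track_core import AnalysisConfig, Track

CFG = AnalysisConfig()


def track_from_dx(dx, dt=4.0, length_um=8.6, gap_after=()):
    """Build a track from per-interval displacements; ``gap_after`` lists
    interval indices stretched to a 3-frame gap."""
    steps = np.ones(len(dx))
    for i in gap_after:
        steps[i] = 3
    times = np.concatenate([[0.0], np.cumsum(steps * dt)])
    positions = np.concatenate([[0.0], np.cumsum(dx)])
    return Track("t", times, positions, filament_length_um=length_um)


class TestLabelIntervals:
    def test_threshold_logic(self):
        tr = track_from_dx([1.0, 1.0, 0.0, -1.0])
        assert list(label_intervals(tr, CFG)) == ["A", "A", "P", "R"]

    def test_all_subthreshold_is_paused(self):
        tr = track_from_dx([0.05, -0.1, 0.13, 0.0])
        assert list(label_intervals(tr, CFG)) == ["P"] * 4

    def test_epsilon_boundary_is_pause(self):
        tr = track_from_dx([CFG.pause_epsilon_um, -CFG.pause_epsilon_um])
        assert list(label_intervals(tr, CFG)) == ["P", "P"]

    def test_gap_interval_unscored(self):
        tr = track_from_dx([1.0, 1.0, 1.0], gap_after=(1,))
        assert list(label_intervals(tr, CFG, 4.0)) == ["A", "U", "A"]

    def test_against_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            times, positions = random_track_arrays(rng)
            tr = Track("t", times, positions, 8.6)
            got = list(label_intervals(tr, CFG, 4.0))
            want = brute_force_labels(times, positions,
                                      CFG.pause_epsilon_um, 4.0)
            assert got == want


class TestSegmentBouts:
    def test_hand_traced_two_bouts(self):
        # P A A P R R P with 1-um moving steps at 4-s intervals
        tr = track_from_dx([0, 1, 1, 0, -1, -1, 0])
        scored = [b for b in segment_bouts(tr, CFG) if b.scored]
        assert [b.direction for b in scored] == ["anterograde", "retrograde"]
        for b in scored:
            assert b.distance_um == pytest.approx(2.0)
            assert b.duration_s == pytest.approx(8.0)
            assert b.velocity_um_s == pytest.approx(0.25)

    def test_bout_at_track_start_is_truncated(self):
        tr = track_from_dx([1, 1, 0])
        bouts = segment_bouts(tr, CFG)
        assert len(bouts) == 1 and bouts[0].truncated == "start"
        assert not bouts[0].scored

    def test_bout_at_track_end_is_truncated(self):
        tr = track_from_dx([0, 1, 1])
        assert segment_bouts(tr, CFG)[0].truncated == "end"

    def test_reversal_without_pause_splits_bouts(self):
        tr = track_from_dx([0, 1, -1, 0])
        scored = [b for b in segment_bouts(tr, CFG) if b.scored]
        assert [b.direction for b in scored] == ["anterograde", "retrograde"]
        assert all(b.duration_s == pytest.approx(4.0) for b in scored)

    def test_single_interval_bout_is_valid(self):
        tr = track_from_dx([0, 1, 0])
        scored = [b for b in segment_bouts(tr, CFG) if b.scored]
        assert len(scored) == 1 and scored[0].distance_um == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(300):
            times, positions = random_track_arrays(rng)
            tr = Track("t", times, positions, 8.6)
            got = [(b.direction, b.start_s, b.end_s, b.distance_um, b.truncated)
                   for b in segment_bouts(tr, CFG, 4.0)]
            want = brute_force_bouts(times, positions,
                                     CFG.pause_epsilon_um, 4.0)
            assert len(got) == len(want)
            for g, w in zip(got, want):
                assert g[0] == w[0] and g[4] == w[4]
                assert g[1] == pytest.approx(w[1])
                assert g[2] == pytest.approx(w[2])
                assert g[3] == pytest.approx(w[3])

    def test_bouts_tile_moving_intervals(self):
        """Every moving interval belongs to exactly one bout."""
        rng = np.random.default_rng(29)
        for _ in range(200):
            times, positions = random_track_arrays(rng)
            tr = Track("t", times, positions, 8.6)
            labels = label_intervals(tr, CFG, 4.0)
            covered = np.zeros(labels.size, int)
            for b in segment_bouts(tr, CFG, 4.0):
                sel = (times[:-1] >= b.start_s - 1e-9) & \
                      (times[1:] <= b.end_s + 1e-9)
                covered += sel
            moving = np.isin(labels, ["A", "R"])
            assert np.all(covered[moving] == 1)
            assert np.all(covered[~moving] == 0)


class TestQualifyTrack:
    def test_qualifying_track(self):
        tr = track_from_dx([0, 2, 2, 2, 2, 2, 0])  # path 10 um, 8 frames
        assert qualify_track(tr, CFG)

    def test_short_filament_rejected(self):
        tr = track_from_dx([0, 2, 2, 2, 2, 2, 0], length_um=1.0)
        assert not qualify_track(tr, CFG)

    def test_path_length_not_net_displacement(self):
        # out-and-back: net 0, path 8 um -> still qualifies on distance,
        # 6.55-um threshold reads path length
        dx = [1.0] * 4 + [-1.0] * 4
        tr = track_from_dx(dx)
        assert sum(dx) == 0
        assert qualify_track(tr, CFG)

    def test_distance_threshold(self):
        tr = track_from_dx([0, 2, 2, 2, 0])  # path 6 um < 6.55
        assert not qualify_track(tr, CFG)

    def test_min_frames_needs_gap_free_run(self):
        # moving far, but every frame separated by a gap: 10 tracked frames,
        # no 3 successive ones
        tr = track_from_dx([2.0] * 9, gap_after=range(9))
        assert not qualify_track(tr, CFG, frame_interval_s=4.0)

    def test_lowering_distance_threshold_is_monotone(self):
        rng = np.random.default_rng(31)
        tracks = [Track("t", *random_track_arrays(rng), 8.6)
                  for _ in range(150)]
        counts = []
        for thr in (80.0, 50.0, 20.0, 5.0):
            cfg = AnalysisConfig(min_total_distance_px=thr)
            counts.append(sum(qualify_track(t, cfg, frame_interval_s=4.0)
                              for t in tracks))
        assert counts == sorted(counts)


class TestClassifyDirection:
    def test_eighty_percent_anterograde(self):
        tr = track_from_dx([0] + [1] * 8 + [-1] * 2 + [0])
        tc = classify_direction(tr, CFG)
        assert tc.direction_class == "anterograde"
        assert tc.moving_time_fraction_antero == pytest.approx(0.8)

    def test_symmetric_is_dual(self):
        tr = track_from_dx([0] + [1] * 5 + [-1] * 5 + [0])
        assert classify_direction(tr, CFG).direction_class == "dual"

    def test_seventy_percent_boundary_inclusive(self):
        tr = track_from_dx([0] + [1] * 7 + [-1] * 3 + [0])
        assert classify_direction(tr, CFG).direction_class == "anterograde"

    def test_retrograde_class(self):
        tr = track_from_dx([0] + [-1] * 9 + [1] + [0])
        assert classify_direction(tr, CFG).direction_class == "retrograde"

    def test_nonmover_raises(self):
        tr = track_from_dx([0.0, 0.05, -0.05, 0.0])
        with pytest.raises(ValueError, match="non-mover"):
            classify_direction(tr, CFG)

    def test_pauses_excluded_from_time_fraction(self):
        # 3 antero + 1 retro moving intervals among many pauses -> 0.75
        tr = track_from_dx([0, 1, 0, 1, 0, 1, 0, -1, 0])
        tc = classify_direction(tr, CFG)
        assert tc.moving_time_fraction_antero == pytest.approx(0.75)

    def test_directed_distance_conservation(self):
        rng = np.random.default_rng(37)
        for _ in range(200):
            tr = Track("t", *random_track_arrays(rng), 8.6)
            try:
                tc = classify_direction(tr, CFG, frame_interval_s=4.0)
            except ValueError:
                continue
            assert tc.directed_distance_antero_um + \
                tc.directed_distance_retro_um == pytest.approx(
                    tc.total_path_um, abs=1e-9)


class TestParameterRecovery:
    def test_retrograde_bout_velocity_control(self, control_cohort_200):
        from nfkin.pipeline import pooled_bout_stats
        _, analyses = control_cohort_200
        stats = pooled_bout_stats(analyses, "retrograde")
        assert stats["n_bouts"] > 500
        assert stats["mean_velocity_um_s"] == pytest.approx(0.32, rel=0.05)

    def test_retrograde_bout_velocity_n256s(self, n256s_cohort_200):
        from nfkin.pipeline import pooled_bout_stats
        _, analyses = n256s_cohort_200
        stats = pooled_bout_stats(analyses, "retrograde")
        assert stats["mean_velocity_um_s"] == pytest.approx(0.40, rel=0.05)
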