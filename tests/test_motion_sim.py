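import numpy as np
import pytest
from dataclasses import replace

from conftest import mean_sem
from nfkin.kymo_eb1 import comet_velocity
from nfkin.motion_sim import (ConditionPreset, calibrate_bouts_per_filament,
                              get_preset, load_preset, save_preset,
                              simulate_comets, simulate_movie)
from nfkin.pipeline import simulate_cohort


class TestCalibration:
    @pytest.mark.parametrize("args,expected", [
        ((4.5, 149.0, 0.27, 19.0), 6.454),    # control anterograde
        ((3.2, 116.0, 0.32, 11.0), 10.298),   # control retrograde
    ])
    def test_closed_form(self, args, expected):
        assert calibrate_bouts_per_filament(*args) == pytest.approx(
            expected, abs=5e-4)

    def test_identity(self):
        for v, d in [(0.1, 5.0), (0.4, 30.0)]:
            assert calibrate_bouts_per_filament(1.0, v * d, v, d) == \
                pytest.approx(1.0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            calibrate_bouts_per_filament(0.0, 100, 0.3, 10)


class TestPresets:
    def test_builtins_exist(self):
        for name in ("control", "n256s", "wt_overexpression"):
            assert get_preset(name).name == name
        with pytest.raises(KeyError):
            get_preset("mystery")

    def test_json_roundtrip(self, tmp_path):
        p = get_preset("control")
        assert load_preset(save_preset(p, tmp_path / "p.json")) == p

    def test_invariant_checks(self):
        with pytest.raises(ValueError):
            replace(get_preset("control"), reversal_probability=0.5)
        with pytest.raises(ValueError):
            replace(get_preset("control"), filament_length_range_um=(10, 2))


class TestSimulateMovie:
    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            simulate_movie(get_preset("control"))

    def test_determinism(self):
        a = simulate_movie(get_preset("control"), seed=9)
        b = simulate_movie(get_preset("control"), seed=9)
        assert len(a.movie.tracks) == len(b.movie.tracks)
        for ta, tb in zip(a.movie.tracks, b.movie.tracks):
            np.testing.assert_array_equal(ta.times, tb.times)
            np.testing.assert_array_equal(ta.positions, tb.positions)
            assert ta.filament_length_um == tb.filament_length_um
        assert a.truth.keys() == b.truth.keys()
        for k in a.truth:
            assert a.truth[k].bouts == b.truth[k].bouts

    def test_zero_reversal_probability_is_unidirectional(self):
        preset = replace(get_preset("control"), reversal_probability=0.0)
        for sim in simulate_cohort(preset, 20, base_seed=4):
            for truth in sim.truth.values():
                assert all(b.direction == truth.primary_direction
                           for b in truth.bouts)

    def test_truth_bouts_tile_moving_path(self, control_cohort_200):
        """Sum of ground-truth bout distances equals each track's total
        path length over moving intervals, exactly."""
        sims, _ = control_cohort_200
        for sim in sims[:50]:
            for track in sim.movie.tracks:
                path = track.path_length_um()  # pause intervals move 0
                truth_dist = sum(b.distance_um
                                 for b in sim.truth[track.track_id].bouts)
                assert truth_dist == pytest.approx(path, abs=1e-8)

    def test_tracks_respect_movie_window(self, control_cohort_200):
        sims, _ = control_cohort_200
        for sim in sims:
            for tr in sim.movie.tracks:
                assert tr.times[0] >= 0 and tr.times[-1] <= 900

    def test_filament_length_distribution(self, control_cohort_200):
        sims, _ = control_cohort_200
        lengths = np.array([t.filament_length_um
                            for s in sims for t in s.movie.tracks])
        assert lengths.min() > 1.3 and lengths.max() < 44.5
        mean, sem = mean_sem(lengths)
        assert abs(mean - 8.6) < 3 * sem

    def test_flux_closure_from_truth(self, control_cohort_200):
        """Generator-level check: observed directed distance per movie,
        scaled to per-hour, converges to the preset flux."""
        sims, _ = control_cohort_200
        preset = get_preset("control")
        for direction, target in [("anterograde", preset.flux_antero_um_per_hr),
                                  ("retrograde", preset.flux_retro_um_per_hr)]:
            per_movie = [4.0 * sum(b.distance_um for tt in s.truth.values()
                                   for b in tt.bouts if b.direction == direction)
                         for s in sims]
            mean, sem = mean_sem(per_movie)
            assert abs(mean - target) < 3 * sem, (direction, mean, sem)

    def test_preferred_direction_share(self, control_cohort_200):
        """About 97% of classified filaments should keep a >=70% preferred
        direction; reversals make the remainder bidirectional."""
        _, analyses = control_cohort_200
        classes = [c.direction_class for a in analyses for c in a.classes]
        preferred = np.mean([c != "dual" for c in classes])
        sem = np.sqrt(0.97 * 0.03 / len(classes))
        assert abs(preferred - 0.97) < 3 * sem + 1e-9


class TestSimulateComets:
    def test_requires_valid_args(self):
        with pytest.raises(ValueError):
            simulate_comets(0, seed=1)
        with pytest.raises(ValueError):
            simulate_comets(10, retro_fraction=1.5, seed=1)
        with pytest.raises(ValueError, match="seed"):
            simulate_comets(10)

    def test_all_anterograde_without_retro_fraction(self):
        traces = simulate_comets(50, retro_fraction=0.0, seed=2)
        assert all(comet_velocity(tr) > 0 for tr in traces)

    def test_frame_spacing_and_duration(self):
        tr = simulate_comets(1, seed=3)[0]
        np.testing.assert_allclose(np.diff(tr.times), 2.0)
        assert tr.times[-1] == pytest.approx(120.0)

    def test_retrograde_count_matches_binomial_mean(self):
        # 2 of 192 comets retrograde on average
        counts = [sum(comet_velocity(tr) < 0 for tr in
                      simulate_comets(192, retro_fraction=2 / 192, seed=s))
                  for s in range(60)]
        mean, sem = mean_sem(counts)
        assert abs(mean - 2.0) < 3 * sem

    def test_speed_recovery(self):
        traces = simulate_comets(500, velocity_mean=0.13, retro_fraction=0.1,
                                 seed=11)
        speeds = np.abs([comet_velocity(tr) for tr in traces])
        mean, sem = mean_sem(speeds)
        assert abs(mean - 0.13) < 3 * sem
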