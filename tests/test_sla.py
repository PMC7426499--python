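"""Quantization, bout segmentation and the five SLA parameters."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flysla import (AnalysisConfig, Trajectory, WalkerParams, compute_profile,
                    plot_track, quantize, segment_bouts, simulate_fly_profile)
from conftest import make_quantized, straight_line_trajectory


class TestQuantize:
    def test_steady_motion_scores_its_true_speed(self):
        # 0.2 mm per frame at 10 fps = 2.0 mm/s; every step is attributed
        # to the quantum containing its starting sample, so a full quantum
        # carries 10 steps
        traj = straight_line_trajectory(0.02 * 10, 31)
        qt = quantize(traj, AnalysisConfig())
        assert len(qt) == 3
        assert qt.mean_speed[0] == pytest.approx(2.0)
        assert qt.mean_speed[1] == pytest.approx(2.0)
        assert bool(qt.is_run[0])

    def test_stationary_fly_rests_at_zero_speed(self):
        traj = straight_line_trajectory(0.0, 30)
        qt = quantize(traj)
        assert np.all(qt.mean_speed[:2] == 0.0)
        assert not qt.is_run.any()

    @pytest.mark.parametrize("step,expected_run", [(0.12109375, False), (0.125, True)])
    def test_rest_run_boundary_only_lower_is_rest(self, step, expected_run):
        # at 8 fps with binary-exact steps: 8 * 0.12109375 = 0.96875 mm/s
        # -> rest; 8 * 0.125 = 1.0 mm/s exactly -> run (only "lower than"
        # the threshold is rest)
        traj = straight_line_trajectory(step, 17, frame_rate=8.0)
        qt = quantize(traj)
        assert bool(qt.is_run[0]) is expected_run

    def test_quantum_with_too_few_detections_is_invalid(self):
        traj = straight_line_trajectory(0.05, 30)
        traj.detected[10:19] = False  # second quantum keeps one sample
        qt = quantize(traj)
        assert not qt.valid[1] and qt.valid[0] and qt.valid[2]
        assert not qt.is_run[1]

    def test_trajectory_shorter_than_one_quantum_rejected(self):
        with pytest.raises(ValueError, match="shorter than one quantum"):
            quantize(straight_line_trajectory(0.01, 5))


class TestSegmentBouts:
    def test_hand_enumerated_bout_lengths(self):
        qt = make_quantized("RRSSRSSSRR", [2, 4, 0.5, 0.5, 3, 0.2, 0.4, 0.4, 2, 4])
        bouts = segment_bouts(qt)
        assert [(b.start_quantum, b.length_quanta) for b in bouts] == \
            [(0, 2), (4, 1), (8, 2)]

    def test_all_rest_gives_no_bouts(self):
        assert segment_bouts(make_quantized("SSSS", [0.1] * 4)) == []

    def test_all_run_gives_one_edge_to_edge_bout(self):
        bouts = segment_bouts(make_quantized("R" * 10, [3.0] * 10))
        assert len(bouts) == 1 and bouts[0].duration == 10.0

    def test_invalid_quantum_breaks_a_bout(self):
        bouts = segment_bouts(make_quantized("RRXRR", [2, 2, 9, 2, 2]))
        assert [(b.start_quantum, b.length_quanta) for b in bouts] == [(0, 2), (3, 2)]


class TestComputeProfile:
    def test_worked_example(self):
        qt = make_quantized("RRSSRSSSRR",
                            [2, 4, 0.5, 0.5, 3, 0.2, 0.4, 0.4, 2, 4])
        prof = compute_profile(qt, segment_bouts(qt))
        assert prof.index_of_activity == pytest.approx(0.5)
        assert prof.run_frequency == pytest.approx(30.0)
        assert prof.running_speed == pytest.approx(3.0)
        assert prof.total_speed == pytest.approx(1.7)
        assert prof.run_bout_time == pytest.approx(5.0 / 3.0)
        # the algebraic identity of the definitions
        assert prof.run_frequency * prof.run_bout_time == \
            pytest.approx(100.0 * prof.index_of_activity)

    def test_all_rest_profile(self):
        qt = make_quantized("SSSS", [0.5, 0.3, 0.2, 0.2])
        prof = compute_profile(qt, segment_bouts(qt))
        assert prof.index_of_activity == 0.0
        assert prof.run_frequency == 0.0
        assert prof.running_speed is None and prof.run_bout_time is None
        assert prof.total_speed == pytest.approx(0.3)

    def test_no_valid_quanta_rejected(self):
        qt = make_quantized("XX", [1, 1])
        with pytest.raises(ValueError, match="no valid quanta"):
            compute_profile(qt, [])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from("RSX"),
                              st.floats(0, 20, allow_nan=False)), min_size=1, max_size=60))
    def test_identity_and_speed_ordering_hold_for_any_record(self, quanta):
        # classification must stay consistent with the drawn speeds
        states = "".join("R" if (s != "X" and v >= 1) else ("X" if s == "X" else "S")
                         for s, v in quanta)
        speeds = [v for _, v in quanta]
        qt = make_quantized(states, speeds)
        if qt.n_valid == 0:
            return
        prof = compute_profile(qt, segment_bouts(qt))
        if prof.run_bout_time is not None:
            assert prof.run_frequency * prof.run_bout_time == \
                pytest.approx(100.0 * prof.index_of_activity, rel=1e-12)
        if prof.running_speed is not None:
            assert prof.total_speed <= prof.running_speed + 1e-12

    def test_balanced_walker_activity_near_half(self):
        # k1 = k2 walker: index of activity approaches the stationary run
        # probability over a long record (quantization inflates it slightly)
        prof, _, _ = simulate_fly_profile(WalkerParams(duration=2000.0, seed=8),
                                          AnalysisConfig())
        assert prof.index_of_activity == pytest.approx(0.5, abs=0.06)

    def test_wall_bias_raises_centrophobia_index(self):
        # straight runners (high heading persistence) make wall-following
        # visible; reflecting walkers stay near the uniform-area baseline
        # (~0.51 of a uniform disk lies beyond 0.7 of the radius)
        cfg = AnalysisConfig()

        def mean_centro(wall_bias):
            vals = [simulate_fly_profile(
                WalkerParams(duration=600.0, seed=s, wall_bias=wall_bias,
                             turning_concentration=20.0), cfg)[0].centrophobia_index
                for s in range(5, 10)]
            return np.mean(vals)

        assert mean_centro(1.0) > mean_centro(0.0) + 0.1


def test_plot_track_writes_figure(tmp_path):
    _, _, traj = simulate_fly_profile(WalkerParams(duration=30.0, seed=2),
                                      AnalysisConfig())
    out = tmp_path / "track.png"
    plot_track(traj, path=out)
    assert out.stat().st_size > 0
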