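"""Behavioral metric computations against geometric and arithmetic oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from pbmstudy import behavior as bh
from pbmstudy import synthdata as sd

from conftest import straight_trajectory


def _two_frame_traj(nose, head, body):
    mk = lambda p: np.tile(np.asarray(p, float), (2, 1))
    return bh.Trajectory(np.array([0.0, 0.1]), mk(nose), mk(head), mk(body))


class TestExplorationDetection:
    """Nose-within-5-cm AND facing criterion for object exploration."""

    @pytest.mark.parametrize(
        "nose, head, exploring",
        [
            ((6.0, 0.0), (5.0, 0.0), True),   # 4 cm away, heading at the object
            ((4.0, 0.0), (3.0, 0.0), False),  # 6 cm away, facing: outside radius
            ((6.0, 0.0), (7.0, 0.0), False),  # 4 cm away, heading 180° off
            ((4.8, 0.0), (3.8, 0.0), False),  # 5.2 cm away, facing: outside radius
        ],
    )
    def test_distance_and_facing_criterion(self, nort_arena, nose, head, exploring):
        # objects at (±10, 0); probe the right-hand object
        traj = _two_frame_traj(nose, head, head)
        flags = bh.detect_exploration(traj, nort_arena)
        assert bool(flags["right"][0]) is exploring

    def test_facing_cone_is_configurable(self, nort_arena):
        # head 5 cm left of the object, heading rotated 30° off the
        # head→object axis: inside a 45° cone, outside a 10° cone
        ang = math.radians(30)
        head = np.array([5.0, 0.0])
        nose = head + np.array([math.cos(ang), math.sin(ang)])
        traj = _two_frame_traj(nose, head, head)
        assert bh.detect_exploration(traj, nort_arena, facing_max_deg=45.0)["right"][0]
        assert not bh.detect_exploration(traj, nort_arena, facing_max_deg=10.0)["right"][0]

    def test_invalid_frames_never_count(self, nort_arena):
        traj = _two_frame_traj((6.0, 0.0), (5.0, 0.0), (5.0, 0.0))
        traj.valid = np.array([False, True])
        flags = bh.detect_exploration(traj, nort_arena)
        assert not flags["right"][0] and flags["right"][1]


class TestDiscriminationIndex:
    @pytest.mark.parametrize(
        "t_novel, t_old, expected",
        [(30.0, 30.0, 0.0), (45.0, 15.0, 0.5), (10.0, 0.0, 1.0), (0.0, 10.0, -1.0)],
    )
    def test_formula(self, t_novel, t_old, expected):
        assert bh.discrimination_index(t_novel, t_old) == pytest.approx(expected)

    def test_zero_exploration_is_excluded_not_zero(self):
        with pytest.raises(bh.UndefinedMetricError):
            bh.discrimination_index(0.0, 0.0)

    @given(
        t_novel=hst.floats(0.0, 600.0),
        t_old=hst.floats(0.0, 600.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_bounded(self, t_novel, t_old):
        if t_novel + t_old <= 0:
            return
        assert -1.0 <= bh.discrimination_index(t_novel, t_old) <= 1.0


class TestSpontaneousAlternation:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            (list("ABCABC"), 1.0),
            (list("ABABAB"), 0.0),
            (list("ABCACB"), 3 / 4),  # triplets ABC, BCA, CAC, ACB
            (list("ABC"), 1.0),
        ],
    )
    def test_triplet_ratio(self, seq, expected):
        assert bh.spontaneous_alternation(seq) == pytest.approx(expected)

    def test_too_few_entries(self):
        with pytest.raises(bh.UndefinedMetricError):
            bh.spontaneous_alternation(["A", "B"])

    @given(hst.lists(hst.sampled_from("ABC"), min_size=3, max_size=60))
    @settings(max_examples=100, derandomize=True)
    def test_bounded(self, seq):
        assert 0.0 <= bh.spontaneous_alternation(seq) <= 1.0


class TestArmEntries:
    def _path_traj(self, points, fps=10.0):
        pts = np.asarray(points, float)
        time_s = np.arange(len(pts)) / fps
        ahead = np.vstack([pts[1:] - pts[:-1], pts[-1:] - pts[-2:-1]])
        norm = np.linalg.norm(ahead, axis=1, keepdims=True)
        u = np.divide(ahead, norm, out=np.zeros_like(ahead), where=norm > 0)
        return bh.Trajectory(time_s, pts + 2.5 * u, pts + 1.5 * u, pts)

    def test_sequence_in_visit_order(self, ymaze_arena):
        a_end = 30.0 * ymaze_arena.arm_axis("A")
        b_end = 30.0 * ymaze_arena.arm_axis("B")
        traj = self._path_traj([a_end, a_end, [0, 0], b_end, b_end])
        assert bh.detect_arm_entries(traj, ymaze_arena) == ["A", "B"]

    def test_shallow_oscillation_is_no_entry(self, ymaze_arena):
        # dip only 20% into arm A, repeatedly: below the 50% depth criterion
        shallow = (ymaze_arena.center_zone_radius_cm + 0.2 * 35) * ymaze_arena.arm_axis("A")
        traj = self._path_traj([[0, 0], shallow, [0, 0], shallow, [0, 0]])
        assert bh.detect_arm_entries(traj, ymaze_arena) == []

    def test_detected_equals_latent_on_simulated_trials(self, ymaze_arena):
        for seed in range(25):
            params = sd.BehaviorSimParams(
                test_kind="ymaze", duration_s=90, frame_rate_hz=15, seed=seed,
                alternation_bias=0.6,
            )
            traj, truth = sd.simulate_trajectory(params, ymaze_arena)
            detected = bh.detect_arm_entries(traj, ymaze_arena)
            assert detected == truth.arm_sequence[: len(detected)]
            assert len(detected) >= len(truth.arm_sequence) - 1  # last may be mid-walk


class TestMwmTraining:
    def test_stationary_mouse_times_out(self, mwm):
        traj = straight_trajectory((-30, -30), (-30, -30), 10, 10, pad_to_s=120)
        m = bh.mwm_trial_metrics(traj, mwm)
        assert m.path_length_cm == 0.0
        assert m.escape_latency_s == 120.0

    def test_straight_swim_latency_and_path(self, mwm):
        # 80 cm dash at 16 cm/s straight onto the platform (at (0, 30))
        start = np.array([0.0, 30.0 - 80.0])
        traj = straight_trajectory(start, (0, 30), 16, 20, pad_to_s=120)
        m = bh.mwm_trial_metrics(traj, mwm)
        # platform circle (radius 5) is entered 75 cm in, i.e. after ~4.7 s
        assert m.escape_latency_s == pytest.approx(75.0 / 16.0, abs=0.1)
        assert m.path_length_cm == pytest.approx(75.0, abs=1.0)
        assert m.mean_speed_cm_s == pytest.approx(16.0, abs=0.2)

    def test_out_of_pool_is_a_calibration_error(self, mwm):
        traj = straight_trajectory((0, 0), (90, 0), 10, 10)
        with pytest.raises(ValueError, match="calibration"):
            bh.mwm_trial_metrics(traj, mwm)

    def test_path_length_stable_under_resampling(self, mwm):
        params = sd.BehaviorSimParams(
            test_kind="mwm_training", duration_s=60, frame_rate_hz=30,
            goal_bias=0.9, heading_noise=0.02, seed=3,
        )
        traj, _ = sd.simulate_trajectory(params, mwm)
        m30 = bh.mwm_trial_metrics(traj, mwm)
        half = bh.Trajectory(
            traj.time_s[::2], traj.nose_xy[::2], traj.head_xy[::2], traj.body_xy[::2]
        )
        m15 = bh.mwm_trial_metrics(half, mwm)
        assert m15.path_length_cm == pytest.approx(m30.path_length_cm, rel=0.02)


class TestMwmProbe:
    def test_parked_at_platform_center(self, mwm_probe):
        c = mwm_probe.platform_center
        traj = straight_trajectory(c, c, 10, 10, pad_to_s=60)
        m = bh.mwm_probe_metrics(traj, mwm_probe)
        assert m.mean_distance_to_platform_cm == pytest.approx(0.0, abs=1e-9)

    def test_parked_30cm_away(self, mwm_probe):
        # platform at (0, 30); park at (0, 0)+... a point 30 cm away in S quadrant
        p = (0.0, -10.0)
        traj = straight_trajectory(p, p, 10, 10, pad_to_s=60)
        m = bh.mwm_probe_metrics(traj, mwm_probe)
        assert m.mean_distance_to_platform_cm == pytest.approx(40.0)
        assert m.quadrant_time_s["S"] == pytest.approx(sum(m.quadrant_time_s.values()))

    def test_quadrant_times_partition_trial_duration(self, mwm_probe):
        params = sd.BehaviorSimParams(
            test_kind="mwm_probe", duration_s=60, frame_rate_hz=15, seed=9
        )
        traj, _ = sd.simulate_trajectory(params, mwm_probe)
        m = bh.mwm_probe_metrics(traj, mwm_probe)
        total = sum(m.quadrant_time_s.values())
        assert total == pytest.approx(60.0, abs=1.5 / 15)


class TestRigidMotionInvariance:
    def test_nort_di_invariant_under_rotation(self):
        params = sd.BehaviorSimParams(
            test_kind="nort", duration_s=60, frame_rate_hz=15,
            novelty_preference=0.8, seed=7,
        )
        arena = bh.nort_arena()
        traj, _ = sd.simulate_trajectory(params, arena)
        di0 = bh.nort_metrics(traj, arena).discrimination_index
        ang = math.radians(37.0)
        R = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
        rot = bh.Trajectory(
            traj.time_s, traj.nose_xy @ R.T, traj.head_xy @ R.T, traj.body_xy @ R.T
        )
        centers = {k: tuple(R @ np.asarray(v)) for k, v in arena.object_centers.items()}
        arena_rot = bh.ArenaSpec(
            kind="nort", side_cm=80.0, object_centers=centers,
            object_radius_cm=arena.object_radius_cm, novel_object_id="right",
        )
        di1 = bh.nort_metrics(rot, arena_rot).discrimination_index
        assert di1 == pytest.approx(di0, abs=1e-12)


class TestGapFilling:
    def test_short_gap_interpolated_long_gap_excluded(self):
        n, fps = 100, 20.0
        t = np.arange(n) / fps
        xy = np.column_stack([np.linspace(0, 10, n), np.zeros(n)])
        lik = np.ones((n, 3))
        lik[10:14, 0] = 0.1  # 0.2 s gap: fillable
        lik[50:80, 0] = 0.1  # 1.5 s gap: too long
        traj = bh.Trajectory(t, xy.copy(), xy.copy(), xy.copy(), lik)
        clean = traj.clean()
        assert clean.valid[10:14].all()
        assert np.allclose(clean.nose_xy[10:14, 0], xy[10:14, 0], atol=1e-9)
        assert not clean.valid[50:80].any()
        assert clean.valid[[49, 80]].all()
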