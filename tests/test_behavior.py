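"""Kinematics and rule-based behavior classification."""

import numpy as np
import pandas as pd
import pytest

import escapekit as ek
from escapekit.behavior import estimate_body_length
from escapekit.core import BehaviorEpoch, Trajectory
from escapekit.errors import FormatError, InsufficientDataError, ParameterError

from conftest import make_kin


def _straight_trajectory(arena, speed_cms, n=90, fps=30.0, away=True):
    """Rigid body moving in a straight line along the threat axis."""
    direction = -1.0 if away else 1.0
    tail_x = 40.0 + direction * speed_cms * np.arange(n) / fps
    tail_y = np.full(n, 13.0)
    bl, ear = 7.0, 0.72 * 7.0
    nose_x = tail_x + direction * bl
    df = pd.DataFrame({
        "frame": np.arange(n), "time_s": np.arange(n) / fps,
        "nose_x": nose_x, "nose_y": tail_y,
        "earL_x": tail_x + direction * ear, "earL_y": tail_y + 1.2,
        "earR_x": tail_x + direction * ear, "earR_y": tail_y - 1.2,
        "tail_x": tail_x, "tail_y": tail_y,
    })
    return Trajectory(df=df, frame_rate_hz=fps)


class TestComputeKinematics:
    def test_straight_motion_away_from_threat(self, arena):
        """Constant 5 cm/s away: signed velocity -5, head cosine 1."""
        traj = _straight_trajectory(arena, 5.0, away=True)
        kin = ek.compute_kinematics(traj, arena)
        mid = slice(10, 80)  # away from smoothing edge effects
        assert np.allclose(kin["speed"][mid], 5.0, atol=1e-6)
        assert np.allclose(kin["v_threat"][mid], -5.0, atol=1e-6)
        assert np.allclose(kin["head_cos"][mid], 1.0, atol=1e-9)

    def test_stationary_pose_is_freeze_eligible(self, arena):
        traj = _straight_trajectory(arena, 0.0, n=300)
        kin = ek.compute_kinematics(traj, arena)
        assert np.allclose(kin["speed"], 0.0)
        assert np.allclose(kin["nose_speed"], 0.0)

    def test_distance_zero_at_threat_zone_boundary(self, arena):
        x = np.array([arena.threat_boundary_x, 0.0])
        assert arena.distance_from_threat(x)[0] == 0.0
        assert arena.distance_from_threat(x)[1] == arena.threat_boundary_x

    def test_single_frame_is_insufficient(self, arena):
        traj = _straight_trajectory(arena, 0.0, n=90)
        traj = Trajectory(df=traj.df.iloc[:1], frame_rate_hz=30.0)
        with pytest.raises(InsufficientDataError):
            ek.compute_kinematics(traj, arena)

    def test_timestamps_must_increase(self, arena):
        df = _straight_trajectory(arena, 1.0).df.copy()
        df.loc[5, "time_s"] = df.loc[4, "time_s"]
        with pytest.raises(FormatError):
            Trajectory(df=df, frame_rate_hz=30.0)


class TestClassifyEscapes:
    def test_run_from_10_to_50_cm(self, arena):
        """One escape of mean speed 5 and traversal 40 cm, by the rules."""
        n = 300  # 10 s: distance goes 10 -> 50 over frames 30..270
        away = np.zeros(n)
        away[30:270] = 5.0
        dist = np.clip(10.0 + np.cumsum(away) / 30.0, None, 50.0)
        kin = make_kin(arena, speed=np.abs(away), v_threat=-away,
                       dist_threat=dist)
        eps = ek.classify_escapes(kin)
        assert len(eps) == 1
        e = eps[0]
        assert e.label == "escape"
        assert e.mean_speed == pytest.approx(5.0)
        assert e.traversal_cm == pytest.approx(40.0, abs=0.2)

    def test_initiation_beyond_30_cm_rejected(self, arena):
        n = 300
        away = np.zeros(n)
        away[30:270] = 5.0
        dist = 50.0 + np.cumsum(away) / 30.0
        kin = make_kin(arena, speed=np.abs(away), v_threat=-away,
                       dist_threat=dist)
        assert ek.classify_escapes(kin) == []
        # the inequality direction is a config switch
        thr = ek.BehaviorThresholds(escape_init_within=False)
        assert len(ek.classify_escapes(kin, thr)) == 1

    def test_stationary_session_yields_empty_list(self, arena):
        kin = make_kin(arena, n=300)
        assert ek.classify_escapes(kin) == []


class TestSimpleBehaviors:
    def test_freeze_of_one_second(self, arena):
        speed = np.full(120, 3.0)
        speed[45:75] = 0.0  # 30 frames = 1.0 s
        kin = make_kin(arena, speed=speed)
        eps = ek.classify_simple_behaviors(kin, ek.BehaviorThresholds(),
                                           "freeze")
        assert len(eps) == 1
        assert eps[0].duration_s == pytest.approx(1.0)

    def test_freeze_below_minimum_duration_rejected(self, arena):
        speed = np.full(120, 3.0)
        speed[45:51] = 0.0  # 6 frames = 0.20 s < 0.33 s
        kin = make_kin(arena, speed=speed)
        assert ek.classify_simple_behaviors(kin, ek.BehaviorThresholds(),
                                            "freeze") == []

    def test_freeze_requires_both_nose_and_tailbase_slow(self, arena):
        speed = np.full(120, 0.0)
        nose = np.full(120, 3.0)  # nose keeps moving
        kin = make_kin(arena, speed=speed, nose_speed=nose)
        assert ek.classify_simple_behaviors(kin, ek.BehaviorThresholds(),
                                            "freeze") == []

    def test_stretch_elongated_and_slow(self, arena):
        bl = np.full(300, 7.0)
        bl[100:160] = 7.0 * 1.3  # 2 s at 1.3x baseline
        speed = np.full(300, 0.5)
        kin = make_kin(arena, speed=speed, body_len=bl)
        eps = ek.classify_simple_behaviors(kin, ek.BehaviorThresholds(),
                                           "stretch")
        assert len(eps) == 1
        # tailbase above 1 cm/s breaks the posture rule
        kin2 = make_kin(arena, speed=np.full(300, 1.5), body_len=bl)
        assert ek.classify_simple_behaviors(kin2, ek.BehaviorThresholds(),
                                            "stretch") == []

    def test_approach_traversal_clause(self, arena):
        n = 300
        toward = np.zeros(n)
        toward[30:120] = 5.0  # 3 s -> 15 cm toward
        dist = 40.0 - np.cumsum(toward) / 30.0
        kin = make_kin(arena, speed=toward, v_threat=toward, dist_threat=dist)
        assert len(ek.classify_simple_behaviors(
            kin, ek.BehaviorThresholds(), "approach")) == 1
        toward2 = np.zeros(n)
        toward2[30:75] = 5.0  # 1.5 s -> 7.5 cm < 10 cm
        dist2 = 40.0 - np.cumsum(toward2) / 30.0
        kin2 = make_kin(arena, speed=toward2, v_threat=toward2,
                        dist_threat=dist2)
        assert ek.classify_simple_behaviors(
            kin2, ek.BehaviorThresholds(), "approach") == []

    def test_walk_perpendicular_displacement(self, arena):
        n = 300
        vy = np.zeros(n)
        vy[30:120] = 4.0  # 12 cm across
        y = np.cumsum(vy) / 30.0 + 5.0
        kin = make_kin(arena, speed=np.abs(vy), v_perp=vy, y=y)
        assert len(ek.classify_simple_behaviors(
            kin, ek.BehaviorThresholds(), "walk")) == 1

    def test_unknown_label_raises(self, arena):
        kin = make_kin(arena, n=10)
        with pytest.raises(ParameterError):
            ek.classify_simple_behaviors(kin, ek.BehaviorThresholds(), "rear")

    def test_body_length_baseline_excludes_elongated_frames(self, arena):
        bl = np.full(300, 7.0)
        bl[0:90] = 9.5  # long elongated stretch should not move the baseline
        kin = make_kin(arena, body_len=bl)
        assert estimate_body_length(kin) == pytest.approx(7.0)


class TestRoundTrip:
    def test_planted_counts_recovered_exactly(self, mixed_session):
        traj, truth, kin = mixed_session
        eps = ek.classify_all(kin)
        for label in ek.core.BEHAVIOR_LABELS:
            want = int((truth["label"] == label).sum())
            got = sum(e.label == label for e in eps)
            assert got == want, label

    @pytest.mark.parametrize("label,violation", [
        ("escape", "proximity"), ("escape", "speed"), ("escape", "traversal"),
        ("approach", "speed"), ("approach", "traversal"),
        ("walk", "speed"), ("walk", "traversal"),
        ("freeze", "duration"),
        ("stretch", "tailspeed"), ("stretch", "elongation"),
    ])
    def test_single_clause_violations_rejected(self, arena, label, violation):
        """Breaking exactly one clause removes the episode; restoring the
        clause restores it."""
        bad = [ek.Episode(label, onset_s=10.0, violate=violation)]
        traj, _ = ek.generate_arena_session(arena, bad, seed=5,
                                            duration_s=60.0)
        kin = ek.compute_kinematics(traj, arena)
        assert ek.classify_all(kin) == []

        good = [ek.Episode(label, onset_s=10.0)]
        traj2, _ = ek.generate_arena_session(arena, good, seed=5,
                                             duration_s=60.0)
        kin2 = ek.compute_kinematics(traj2, arena)
        assert sum(e.label == label
                   for e in ek.classify_all(kin2)) == 1

    def test_classification_is_deterministic(self, mixed_session):
        _, _, kin = mixed_session
        a = ek.classify_all(kin)
        b = ek.classify_all(kin)
        assert [(e.label, e.onset, e.offset) for e in a] \
            == [(e.label, e.onset, e.offset) for e in b]


class TestRunExtraction:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.booleans(), min_size=1, max_size=300),
           st.integers(1, 5))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_merged_runs_are_disjoint_ordered_and_cover_mask(self, mask, gap):
        from escapekit.behavior import _merge_runs, _runs
        mask = np.array(mask, dtype=bool)
        runs = _runs(mask)
        # runs exactly cover the True positions
        covered = np.zeros(len(mask), dtype=bool)
        for s, e in runs:
            assert 0 <= s < e <= len(mask)
            assert mask[s:e].all()
            covered[s:e] = True
        assert np.array_equal(covered, mask)
        merged = _merge_runs(runs, gap)
        # merged runs are ordered, separated by at least `gap`, and cover
        # at least the original mask
        for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
            assert s2 - e1 >= gap
        mcov = np.zeros(len(mask), dtype=bool)
        for s, e in merged:
            mcov[s:e] = True
        assert (mcov | ~mask).all()


class TestSummarize:
    def test_empty_epochs(self, arena):
        kin = make_kin(arena, n=100)
        s = ek.summarize_session([], kin)
        assert s["n_escape"] == 0 and s["n_freeze"] == 0
        assert np.isnan(s["mean_freeze_bout_s"])
        assert np.isnan(s["mean_escape_speed_cms"])

    def test_mean_freeze_bout(self, arena):
        kin = make_kin(arena, n=300)
        eps = [BehaviorEpoch("freeze", 0, 30, 1.0),
               BehaviorEpoch("freeze", 100, 190, 3.0)]
        s = ek.summarize_session(eps, kin)
        assert s["mean_freeze_bout_s"] == pytest.approx(2.0)
        assert s["n_freeze"] == 2

    def test_counts_match_schedule(self, mixed_session):
        traj, truth, kin = mixed_session
        s = ek.summarize_session(ek.classify_all(kin), kin)
        for label in ek.core.BEHAVIOR_LABELS:
            assert s[f"n_{label}"] == (truth["label"] == label).sum()
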