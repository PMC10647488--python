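"""Joint angles, hyperextension convention, ROM, cycle detection."""

import numpy as np
import pytest

from hydromocap.kinematics import (
    JOINT_DEFINITIONS,
    AngleSeries,
    JointDefinition,
    RomSummary,
    detect_cycles,
    joint_angle,
    joint_angle_series,
    summarize_rom,
)
from hydromocap.reconstruction import Trajectory3D
from hydromocap.synthetic import (
    camera_frame_joint_definitions,
    default_front_limb,
    make_default_rig,
    simulate_swim,
)

from conftest import random_rigid_transform


class TestJointAngle:
    def test_right_angle(self):
        assert np.isclose(
            joint_angle([1, 0, 0], [0, 0, 0], [0, 1, 0], lateral_axis=[0, 0, 1]), 90.0
        )

    def test_collinear_is_straight_joint(self):
        assert np.isclose(joint_angle([-1, 0, 0], [0, 0, 0], [1, 0, 0]), 180.0)

    def test_checkerboard_triangle_angle_at_ml(self):
        # TL-ML-TR with the board's reference coordinates: 101.31 degrees
        ang = joint_angle([0, 0, 0], [240, 240, 0], [600, 0, 0], lateral_axis=[0, 0, 1])
        assert abs(ang - 101.31) < 0.01

    def test_hyperextension_exceeds_180(self):
        """A fetlock rotated past straight reports > 180 deg, as the hind
        fetlock does at peak extension (203 deg)."""
        theta = np.radians(203.0)
        lateral = np.array([0.0, 0.0, 1.0])
        v1 = np.array([1.0, 0.0, 0.0])
        # rotate v1 about +z by theta: the distal segment direction
        v2 = np.array([np.cos(theta), np.sin(theta), 0.0])
        ang = joint_angle(v1, [0, 0, 0], v2, lateral_axis=lateral)
        assert np.isclose(ang, 203.0, atol=1e-9)

    def test_zero_length_vector_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            joint_angle([0, 0, 0], [0, 0, 0], [1, 0, 0])

    def test_invariant_under_common_rigid_transform(self, rng):
        """Angle invariant when points and lateral axis move together."""
        for _ in range(25):
            pts = rng.uniform(-500, 500, (3, 3))
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            a0 = joint_angle(pts[0], pts[1], pts[2], lateral_axis=axis)
            t = random_rigid_transform(rng)
            moved = t.apply(pts)
            a1 = joint_angle(
                moved[0], moved[1], moved[2], lateral_axis=t.rotation @ axis
            )
            assert abs(a0 - a1) < 1e-9

    def test_scale_invariance_of_limb_vectors(self, rng):
        pts = rng.uniform(-100, 100, (3, 3))
        vertex = pts[1]
        scaled_prox = vertex + 7.5 * (pts[0] - vertex)
        scaled_dist = vertex + 0.2 * (pts[2] - vertex)
        assert np.isclose(
            joint_angle(pts[0], vertex, pts[2]),
            joint_angle(scaled_prox, vertex, scaled_dist),
            atol=1e-9,
        )


class TestJointAngleSeries:
    def test_swim_ground_truth_matches_prescription(self):
        """Angles recomputed from the generated marker positions equal the
        prescribed sinusoids (forward/inverse consistency, noiseless)."""
        rig = make_default_rig()
        _, truth_angles, truth_trajs = simulate_swim(rig, noise_px=0.0, seed=4)
        defs = camera_frame_joint_definitions(JOINT_DEFINITIONS)
        series = joint_angle_series(truth_trajs, defs, rig.frame_rate)
        for name, s in series.items():
            assert np.abs(s.angles_deg - truth_angles[name].angles_deg).max() < 1e-6

    def test_missing_marker_names_joint(self):
        trajs = {"shoulder": Trajectory3D("shoulder", [0], [[0, 0, 0]], "c")}
        with pytest.raises(KeyError, match="shoulder"):
            joint_angle_series(trajs, JOINT_DEFINITIONS[:1])

    def test_frame_dropped_when_any_marker_invisible(self):
        trajs = {
            "scapular_spine": Trajectory3D("scapular_spine", [0, 1, 2], np.eye(3) * 100 + 1, "c"),
            "shoulder": Trajectory3D("shoulder", [0, 2], [[5, 0, 0], [0, 5, 0]], "c"),
            "elbow": Trajectory3D("elbow", [0, 1, 2], -np.eye(3) * 100 - 1, "c"),
        }
        series = joint_angle_series(trajs, JOINT_DEFINITIONS[:1])
        assert np.array_equal(series["shoulder"].frames, [0, 2])

    def test_rigid_transform_of_scene_leaves_series_unchanged(self, rng):
        rig = make_default_rig()
        _, _, truth_trajs = simulate_swim(rig, n_cycles=1, noise_px=0.0, seed=4)
        t = random_rigid_transform(rng, "camera:cam1", "elsewhere")
        defs = camera_frame_joint_definitions(JOINT_DEFINITIONS)
        moved_defs = tuple(
            JointDefinition(
                d.name, d.proximal, d.vertex, d.distal,
                tuple(t.rotation @ np.asarray(d.lateral_axis)),
            )
            for d in defs
        )
        s0 = joint_angle_series(truth_trajs, defs)
        moved = {lbl: tr.transformed(t) for lbl, tr in truth_trajs.items()}
        s1 = joint_angle_series(moved, moved_defs)
        for name in s0:
            assert np.abs(s0[name].angles_deg - s1[name].angles_deg).max() < 1e-9


class TestRomSummary:
    def test_reported_shoulder_convention(self):
        """Series spanning 102-119 deg: ROM = 119 - 102 = 17 deg."""
        s = AngleSeries("shoulder", np.arange(4), [110.0, 102.0, 119.0, 111.0])
        r = summarize_rom(s)
        assert r.maximal_flexion == 102.0
        assert r.maximal_extension == 119.0
        assert r.rom == 17.0

    def test_constant_series_has_zero_rom(self):
        r = summarize_rom(AngleSeries("j", np.arange(5), np.full(5, 91.0)))
        assert r.rom == 0.0

    def test_sinusoid_rom_is_twice_amplitude(self):
        t = np.arange(3000)
        angles = 120.0 + 35.0 * np.sin(2 * np.pi * t / 180.0)
        r = summarize_rom(AngleSeries("j", t, angles))
        assert abs(r.rom - 70.0) < 0.05

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_rom(AngleSeries("j", [], []))

    def test_rom_identity_holds_exactly(self):
        r = RomSummary(69.0, 168.0)
        assert r.rom == r.maximal_extension - r.maximal_flexion == 99.0


class TestCycleDetection:
    def test_swim_cycle_duration_recovered(self):
        """A 1.5 s joint oscillation at 120 fps over 3 cycles yields
        cycles of 1.5 s within 10 ms."""
        fps = 120.0
        t = np.arange(int(4.5 * fps)) / fps
        angles = 110.0 + 30.0 * np.sin(2 * np.pi * t / 1.5)
        s = AngleSeries("carpus", np.arange(len(t)), angles, fps)
        _, durations = detect_cycles(s, min_period_s=1.0)
        assert len(durations) == 2
        assert all(abs(d - 1.5) <= 0.01 for d in durations)

    def test_constant_series_has_no_cycles(self):
        s = AngleSeries("j", np.arange(600), np.full(600, 100.0), 120.0)
        boundaries, durations = detect_cycles(s)
        assert boundaries == [] and durations == []

    def test_two_planted_periods_recovered(self):
        fps = 120.0
        p1, p2 = 1.4, 1.6
        t1 = np.arange(int(p1 * fps)) / fps
        t2 = np.arange(int(p2 * fps)) / fps
        angles = np.concatenate(
            [
                100 - 30 * np.cos(2 * np.pi * t1 / p1),
                100 - 30 * np.cos(2 * np.pi * t2 / p2),
                [100 - 30],
            ]
        )
        # peaks sit at the middle of each period segment
        s = AngleSeries("j", np.arange(len(angles)), angles, fps)
        _, durations = detect_cycles(s, min_period_s=1.0)
        expected = (p1 + p2) / 2.0  # peak-to-peak spacing spans the boundary
        assert len(durations) == 1
        assert abs(durations[0] - expected) <= 1.0 / fps
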