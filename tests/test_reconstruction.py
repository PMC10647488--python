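"""DLT triangulation, rigid registration, frame unification, pool frame."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hydromocap.geometry import (
    CameraModel,
    Distortion,
    Intrinsics,
    RigidTransform,
    projection_matrix,
)
from hydromocap.reconstruction import (
    GlobalFrameSpec,
    MarkerTrack2D,
    Trajectory3D,
    build_global_frame,
    estimate_transition,
    interpolate_gaps,
    reconstruct_pair,
    triangulate_dlt,
    triangulate_dlt_batch,
    unify_frames,
)
from hydromocap.synthetic import (
    make_default_rig,
    simulate_checkerboard_pass,
    simulate_plumb_and_waterline,
)

from conftest import random_rigid_transform


def _stereo_cameras():
    intr = Intrinsics(800.0, 800.0, 1351.5, 759.5)
    cam_a = CameraModel("a", intr, Distortion(), RigidTransform.identity("pair"))
    pose_b = RigidTransform(
        Rotation.from_euler("y", 5, degrees=True).as_matrix(),
        np.array([-500.0, 0.0, 0.0]),
        source_frame="pair",
        target_frame="camera:b",
    )
    cam_b = CameraModel("b", intr, Distortion(), pose_b)
    return cam_a, cam_b


class TestTriangulation:
    def test_noiseless_point_recovered_exactly(self):
        cam_a, cam_b = _stereo_cameras()
        p = np.array([120.0, -40.0, 1500.0])
        from hydromocap.geometry import project

        res = triangulate_dlt(
            project(p, cam_a), project(p, cam_b),
            projection_matrix(cam_a), projection_matrix(cam_b),
        )
        assert np.abs(res.point - p).max() < 1e-6
        assert not res.flagged
        assert max(res.residuals) < 1e-8

    def test_noisy_points_agree_with_ray_midpoint_oracle(self, rng):
        """Independent oracle: midpoint of the closest-approach segment of
        the two back-projected rays."""
        cam_a, cam_b = _stereo_cameras()
        from hydromocap.geometry import project

        pts = rng.uniform([-600, -400, 900], [600, 400, 2200], size=(1000, 3))
        pix_a = project(pts, cam_a) + rng.normal(0, 0.5, (1000, 2))
        pix_b = project(pts, cam_b) + rng.normal(0, 0.5, (1000, 2))
        dlt_pts, _, _, _ = triangulate_dlt_batch(
            pix_a, pix_b, projection_matrix(cam_a), projection_matrix(cam_b)
        )

        # oracle: rays from camera centres through the ideal pixels
        def ray(cam, pix):
            intr = cam.intrinsics
            d = np.stack(
                [
                    (pix[:, 0] - intr.cx) / intr.fx,
                    (pix[:, 1] - intr.cy) / intr.fy,
                    np.ones(len(pix)),
                ],
                axis=1,
            )
            inv = cam.pose.invert()
            origin = inv.translation
            return origin, d @ inv.rotation.T

        o1, d1 = ray(cam_a, pix_a)
        o2, d2 = ray(cam_b, pix_b)
        mids = []
        for i in range(len(pts)):
            a, b = d1[i], d2[i]
            w = o2 - o1
            aa, bb, ab = a @ a, b @ b, a @ b
            denom = aa * bb - ab * ab
            s = (bb * (w @ a) - ab * (w @ b)) / denom
            t = (ab * (w @ a) - aa * (w @ b)) / denom
            mids.append(((o1 + s * a) + (o2 + t * b)) / 2.0)
        mids = np.asarray(mids)
        median_dev = np.median(np.linalg.norm(dlt_pts - mids, axis=1))
        assert median_dev < 1.0  # mm

    def test_point_behind_cameras_is_flagged(self):
        cam_a, cam_b = _stereo_cameras()
        # pixels chosen so the DLT solution sits behind both cameras
        p_behind = np.array([50.0, 20.0, -1500.0])
        proj_a = projection_matrix(cam_a)
        proj_b = projection_matrix(cam_b)
        hom_a = proj_a[:, :3] @ p_behind + proj_a[:, 3]
        hom_b = proj_b[:, :3] @ p_behind + proj_b[:, 3]
        res = triangulate_dlt(
            hom_a[:2] / hom_a[2], hom_b[:2] / hom_b[2], proj_a, proj_b
        )
        assert res.flagged
        assert res.reason == "negative depth"

    def test_high_residual_flagged_not_dropped(self):
        cam_a, cam_b = _stereo_cameras()
        from hydromocap.geometry import project

        p = np.array([120.0, -40.0, 1500.0])
        # a vertical offset violates the (mostly horizontal) epipolar
        # geometry, so no 3D point can explain both observations
        res = triangulate_dlt(
            project(p, cam_a) + np.array([0.0, 25.0]), project(p, cam_b),
            projection_matrix(cam_a), projection_matrix(cam_b),
        )
        assert res.flagged and "residual" in res.reason
        assert np.isfinite(res.point).all()


class TestReconstructPair:
    def _tracks(self, cam, label, frames, points):
        from hydromocap.geometry import project

        return MarkerTrack2D(cam.camera_id, label, frames, project(points, cam))

    def test_noiseless_limb_reconstructed_exactly(self, rng):
        cam_a, cam_b = _stereo_cameras()
        frames = np.arange(50)
        pts = rng.uniform([-300, -300, 1200], [300, 300, 1800], size=(50, 3))
        tracks_a = [self._tracks(cam_a, "carpus", frames, pts)]
        tracks_b = [self._tracks(cam_b, "carpus", frames, pts)]
        stereo = cam_a.pose.invert().compose(cam_b.pose)
        out = reconstruct_pair(tracks_a, tracks_b, cam_a, cam_b, stereo)
        assert np.abs(out["carpus"].points - pts).max() < 1e-6
        assert out["carpus"].coordinate_frame == "camera:a"

    def test_label_seen_by_one_camera_is_empty(self, rng):
        cam_a, cam_b = _stereo_cameras()
        frames = np.arange(10)
        pts = np.tile([0.0, 0.0, 1500.0], (10, 1))
        tracks_a = [self._tracks(cam_a, "hoof", frames, pts)]
        stereo = cam_a.pose.invert().compose(cam_b.pose)
        out = reconstruct_pair(tracks_a, [], cam_a, cam_b, stereo)
        assert out == {}

    def test_alternating_visibility_reconstructs_intersection(self, rng):
        cam_a, cam_b = _stereo_cameras()
        pts = rng.uniform([-200, -200, 1200], [200, 200, 1800], size=(20, 3))
        frames_a = np.arange(0, 20, 2)  # even frames
        frames_b = np.arange(0, 20, 3)  # every third frame
        tracks_a = [self._tracks(cam_a, "m", frames_a, pts[frames_a])]
        tracks_b = [self._tracks(cam_b, "m", frames_b, pts[frames_b])]
        stereo = cam_a.pose.invert().compose(cam_b.pose)
        out = reconstruct_pair(tracks_a, tracks_b, cam_a, cam_b, stereo)
        expected = np.intersect1d(frames_a, frames_b)
        assert np.array_equal(out["m"].frames, expected)


class TestTransitionEstimation:
    def test_identical_sets_give_identity(self, rng):
        pts = rng.uniform(-500, 500, (10, 3))
        t, rms = estimate_transition(pts, pts)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(t.translation, 0.0, atol=1e-12)
        assert rms < 1e-12

    def test_random_rigid_motion_recovered_exactly(self, rng):
        for _ in range(10):
            pts = rng.uniform(-1000, 1000, (50, 3))
            truth = random_rigid_transform(rng)
            t, rms = estimate_transition(pts, truth.apply(pts))
            assert np.abs(t.rotation - truth.rotation).max() < 1e-9
            assert np.abs(t.translation - truth.translation).max() < 1e-6
            assert rms < 1e-9

    def test_reflection_still_yields_proper_rotation(self, rng):
        pts = rng.uniform(-500, 500, (30, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        t, rms = estimate_transition(pts, mirrored)
        assert np.isclose(np.linalg.det(t.rotation), 1.0, atol=1e-9)
        assert rms > 10.0  # the reflection cannot be explained rigidly

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="collinear"):
            estimate_transition(pts, pts)

    def test_too_few_points_rejected(self):
        pts = np.eye(3)[:2]
        with pytest.raises(ValueError, match=">= 3"):
            estimate_transition(pts, pts)

    def test_zero_residual_iff_exactly_rigid(self, rng):
        pts = rng.uniform(-500, 500, (20, 3))
        truth = random_rigid_transform(rng)
        _, rms_rigid = estimate_transition(pts, truth.apply(pts))
        _, rms_bent = estimate_transition(
            pts, truth.apply(pts) + rng.normal(0, 5.0, (20, 3))
        )
        assert rms_rigid < 1e-9 and rms_bent > 1.0


def _noiseless_reconstruction(duration_s=4.0):
    """Reconstruct the reference points with ground-truth calibration."""
    from hydromocap.reconstruction import undistort_tracks

    rig = make_default_rig()
    _, tracks, truth = simulate_checkerboard_pass(
        rig, duration_s=duration_s, noise_px=0.0, seed=5, view_stride=10**9
    )
    cameras = {c.camera_id: c for c in rig.cameras}
    local_cams = {
        cid: CameraModel(cid, c.intrinsics, c.distortion,
                         RigidTransform.identity(f"camera:{cid}"))
        for cid, c in cameras.items()
    }
    und = undistort_tracks(tracks, cameras)
    pair_trajs = []
    for i, j in rig.pair_indices:
        a, b = rig.cameras[i].camera_id, rig.cameras[j].camera_id
        ta = [t for t in und if t.camera_id == a]
        tb = [t for t in und if t.camera_id == b]
        trajs = reconstruct_pair(
            ta, tb, local_cams[a], local_cams[b], rig.stereo_transform(i, j)
        )
        trajs = {lbl: t for lbl, t in trajs.items() if len(t.frames)}
        if trajs:
            pair_trajs.append(trajs)
    return rig, pair_trajs, truth


class TestUnifyFrames:
    def test_noiseless_unification_matches_ground_truth(self):
        _, pair_trajs, truth = _noiseless_reconstruction()
        unified = unify_frames(pair_trajs)
        for lbl, t in unified.items():
            gt = truth[lbl]
            idx = np.searchsorted(gt.frames, t.frames)
            assert np.abs(t.points - gt.points[idx]).max() < 1e-5

    def test_single_pair_is_passthrough(self):
        _, pair_trajs, _ = _noiseless_reconstruction()
        out = unify_frames(pair_trajs[:1])
        for lbl in out:
            assert np.array_equal(out[lbl].frames, pair_trajs[0][lbl].frames)
            assert np.allclose(out[lbl].points, pair_trajs[0][lbl].points)

    def test_pairwise_distances_invariant_under_unification(self):
        """Rigid maps preserve distances between simultaneously seen points."""
        _, pair_trajs, _ = _noiseless_reconstruction()
        unified = unify_frames(pair_trajs)
        cur = pair_trajs[-1]
        labels = [lbl for lbl in cur if len(cur[lbl].frames) > 0]
        a, b = labels[0], labels[1]
        common = np.intersect1d(cur[a].frames, cur[b].frames)[:20]
        for f in common:
            d_pair = np.linalg.norm(
                cur[a].points[np.searchsorted(cur[a].frames, f)]
                - cur[b].points[np.searchsorted(cur[b].frames, f)]
            )
            d_uni = np.linalg.norm(
                unified[a].points[np.searchsorted(unified[a].frames, f)]
                - unified[b].points[np.searchsorted(unified[b].frames, f)]
            )
            assert np.isclose(d_pair, d_uni, rtol=1e-9, atol=1e-6)

    def test_insufficient_overlap_names_the_pair(self):
        t1 = {"m": Trajectory3D("m", np.arange(5), np.random.rand(5, 3), "p1")}
        t2 = {"x": Trajectory3D("x", np.arange(5), np.random.rand(5, 3), "p2")}
        with pytest.raises(ValueError, match="pairs 1 and 2"):
            unify_frames([t1, t2])


class TestGlobalFrame:
    def test_canonical_layout_gives_identity_rotation(self):
        spec = GlobalFrameSpec(
            plumb_lines=[np.array([[0.0, 0, 1000], [0, 0, 0]])],
            waterline_points=np.array([[0.0, 0, 1000], [0, 500, 1000], [0, 900, 1000]]),
            coordinate_frame="c",
        )
        t = build_global_frame(spec)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)

    def test_synthetic_rig_pool_frame_recovered(self):
        rig = make_default_rig()
        spec, truth = simulate_plumb_and_waterline(rig)
        t = build_global_frame(spec)
        assert np.abs(t.rotation - truth.rotation).max() < 1e-9
        assert np.abs(t.translation - truth.translation).max() < 1e-6
        # transformed plumb direction is exactly +z
        up = t.rotation @ (spec.plumb_lines[0][0] - spec.plumb_lines[0][1])
        up /= np.linalg.norm(up)
        assert np.allclose(up, [0, 0, 1], atol=1e-9)

    def test_output_rotation_is_proper(self, rng):
        spec, _ = simulate_plumb_and_waterline(make_default_rig())
        t = build_global_frame(spec)
        assert np.allclose(t.rotation.T @ t.rotation, np.eye(3), atol=1e-9)
        assert np.isclose(np.linalg.det(t.rotation), 1.0, atol=1e-9)

    def test_near_parallel_plumb_and_waterline_rejected(self):
        spec = GlobalFrameSpec(
            plumb_lines=[np.array([[0.0, 0, 1000], [0, 0, 0]])],
            waterline_points=np.array([[0.0, 0, 0], [0, 30, 1000]]),
            coordinate_frame="c",
        )
        with pytest.raises(ValueError, match="parallel"):
            build_global_frame(spec)


class TestGapInterpolation:
    def _traj(self, frames, points):
        return Trajectory3D("m", np.asarray(frames), np.asarray(points, float), "c")

    def test_no_gaps_unchanged(self):
        t = self._traj([0, 1, 2], np.arange(9).reshape(3, 3))
        out = interpolate_gaps(t)
        assert np.array_equal(out.frames, t.frames)

    def test_single_missing_frame_is_linear_midpoint(self):
        t = self._traj([0, 2], [[0, 0, 0], [2, 2, 2]])
        out = interpolate_gaps(t)
        assert np.array_equal(out.frames, [0, 1, 2])
        assert np.allclose(out.points[1], [1, 1, 1])

    def test_gap_beyond_threshold_left_missing(self):
        t = self._traj([0, 21], [[0, 0, 0], [2, 2, 2]])
        out = interpolate_gaps(t, max_gap_frames=12)
        assert np.array_equal(out.frames, [0, 21])
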