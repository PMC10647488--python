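"""Planar intrinsic calibration and stereo relative-pose estimation."""

import logging

import numpy as np
import pytest

from hydromocap.calibration import (
    BoardModel,
    BoardObservation,
    DegenerateConfigurationError,
    calibrate_intrinsics,
    calibrate_stereo,
    estimate_board_pose,
    estimate_homography,
)
from hydromocap.geometry import (
    CameraModel,
    Distortion,
    Intrinsics,
    RigidTransform,
    project,
    rotation_angle_deg,
)
from hydromocap.synthetic import make_default_rig, simulate_board_views

BOARD = BoardModel(n_rows=7, n_cols=10, square_size=50.0)


@pytest.fixture(scope="module")
def camera():
    return CameraModel(
        "camA",
        Intrinsics(800.0, 800.0, 1351.5, 759.5),
        Distortion(k1=-0.25, k2=0.05),
        RigidTransform.identity(),
    )


class TestHomography:
    def test_identity_when_pixels_equal_plane_coordinates(self):
        pts = np.array([[0.0, 0], [100, 0], [100, 80], [0, 80], [50, 40]])
        h = estimate_homography(pts, pts)
        assert np.allclose(h, np.eye(3), atol=1e-10)

    def test_reproduces_synthetic_camera_view_of_plane(self, rng):
        cam = CameraModel("c", Intrinsics(900.0, 920.0, 1300.0, 700.0))
        plane = rng.uniform([0, 0], [600, 480], size=(40, 2))
        world = np.column_stack([plane, np.full(len(plane), 0.0)])
        # place the plane at depth via a rigid offset
        world[:, 2] = 1500.0
        pixels = project(world, cam)
        h = estimate_homography(plane, pixels)
        hom = np.column_stack([plane, np.ones(len(plane))]) @ h.T
        assert np.abs(hom[:, :2] / hom[:, 2:3] - pixels).max() < 1e-8

    def test_three_points_is_underdetermined(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 1]])
        with pytest.raises(DegenerateConfigurationError):
            estimate_homography(pts, pts)


class TestIntrinsicCalibration:
    def test_noiseless_views_recover_focal_exactly(self, camera):
        obs, _ = simulate_board_views(camera, BOARD, n_views=20, noise_px=0.0, seed=7)
        result = calibrate_intrinsics(BOARD, obs)
        assert abs(result.intrinsics.fx - 800.0) / 800.0 < 0.001
        assert result.rmse_px < 1e-6
        assert abs(result.distortion.k1 - (-0.25)) < 1e-6

    def test_noisy_views_rmse_matches_noise_level(self, camera):
        obs, _ = simulate_board_views(camera, BOARD, n_views=20, noise_px=0.5, seed=8)
        result = calibrate_intrinsics(BOARD, obs)
        assert 0.3 < result.rmse_px < 0.7
        assert abs(result.intrinsics.fx - 800.0) / 800.0 < 0.01

    def test_two_views_rejected(self, camera):
        obs, _ = simulate_board_views(camera, BOARD, n_views=2, noise_px=0.0, seed=9)
        with pytest.raises(ValueError, match=">= 3 views"):
            calibrate_intrinsics(BOARD, obs)

    def test_near_parallel_views_are_degenerate(self, camera):
        """Fronto-parallel boards leave the focal length unidentifiable."""
        pts = BOARD.corner_points()
        obs = []
        for i, depth in enumerate((1000.0, 1300.0, 1700.0, 2100.0)):
            shift = np.array([-200.0 + 120.0 * i, -150.0, depth])
            pix = project(pts + shift, camera)
            obs.append(BoardObservation(f"v{i}", camera.camera_id, np.arange(len(pts)), pix))
        with pytest.raises(DegenerateConfigurationError, match="near-parallel"):
            calibrate_intrinsics(BOARD, obs)

    def test_k3_fixed_below_ten_views(self, camera):
        obs, _ = simulate_board_views(camera, BOARD, n_views=5, noise_px=0.2, seed=10)
        result = calibrate_intrinsics(BOARD, obs)
        assert result.distortion.k3 == 0.0


class TestBoardPose:
    def test_noiseless_pose_recovery(self, camera):
        obs, poses = simulate_board_views(camera, BOARD, n_views=3, noise_px=0.0, seed=11)
        for o, truth in zip(obs, poses):
            pose, rmse = estimate_board_pose(
                BOARD, o.corner_ids, o.pixels, camera.intrinsics, camera.distortion
            )
            assert rotation_angle_deg(pose.rotation.T @ truth.rotation) < 1e-6
            assert np.abs(pose.translation - truth.translation).max() < 1e-3
            assert rmse < 1e-8

    def test_frontal_board_depth(self, camera):
        """Board parallel to the image plane at known depth: t_z is that depth."""
        pts = BOARD.corner_points()
        depth = 1500.0
        shift = np.array([-225.0, -150.0, depth])
        pix = project(pts + shift, camera)
        pose, _ = estimate_board_pose(
            BOARD, np.arange(len(pts)), pix, camera.intrinsics, camera.distortion
        )
        assert abs(pose.translation[2] - depth) < 1e-6

    def test_noisy_residual_bounded_by_noise(self, camera, rng):
        obs, _ = simulate_board_views(camera, BOARD, n_views=1, noise_px=0.5, seed=12)
        _, rmse = estimate_board_pose(
            BOARD, obs[0].corner_ids, obs[0].pixels, camera.intrinsics, camera.distortion
        )
        assert rmse <= 0.7  # about the injected 0.5 px noise


def _paired_views(rig, i, j, n_views, noise_px, seed):
    """Board poses seen simultaneously by rig cameras i and j."""
    rng = np.random.default_rng(seed)
    from scipy.spatial.transform import Rotation

    cam_a, cam_b = rig.cameras[i], rig.cameras[j]
    pts = BOARD.corner_points()
    center = pts.mean(axis=0)
    mid_x = -(cam_a.pose.translation[0] + cam_b.pose.translation[0]) / 2.0
    obs_a, obs_b = [], []
    k = 0
    while len(obs_a) < n_views:
        k += 1
        if k > 500 * n_views:
            raise RuntimeError("could not generate paired views")
        angles = np.radians(rng.uniform([-30, -30, -180], [30, 30, 180]))
        r = Rotation.from_euler("xyz", angles).as_matrix()
        world_target = np.array(
            [mid_x + rng.uniform(-300, 300), rng.uniform(-200, 200), rng.uniform(1100, 1700)]
        )
        t = world_target - r @ center
        world = pts @ r.T + t
        from hydromocap.geometry import project_valid

        pix_a, vis_a = project_valid(world, cam_a)
        pix_b, vis_b = project_valid(world, cam_b)
        if not (vis_a.all() and vis_b.all()):
            continue
        if noise_px > 0:
            pix_a = pix_a + rng.normal(0, noise_px, pix_a.shape)
            pix_b = pix_b + rng.normal(0, noise_px, pix_b.shape)
        vid = f"v{len(obs_a):03d}"
        obs_a.append(BoardObservation(vid, cam_a.camera_id, np.arange(len(pts)), pix_a))
        obs_b.append(BoardObservation(vid, cam_b.camera_id, np.arange(len(pts)), pix_b))
    return obs_a, obs_b


class TestStereoCalibration:
    def test_known_baseline_recovered_noiselessly(self):
        rig = make_default_rig()
        obs_a, obs_b = _paired_views(rig, 0, 1, n_views=20, noise_px=0.0, seed=13)
        cam_a, cam_b = rig.cameras[0], rig.cameras[1]
        res = calibrate_stereo(
            BOARD, obs_a, obs_b,
            cam_a.intrinsics, cam_a.distortion, cam_b.intrinsics, cam_b.distortion,
        )
        truth = rig.stereo_transform(0, 1)
        baseline = np.linalg.norm(res.transform.translation)
        assert abs(baseline - 500.0) < 1e-3
        assert np.abs(res.transform.translation - truth.translation).max() < 1e-3
        assert rotation_angle_deg(res.transform.rotation.T @ truth.rotation) < 1e-5

    def test_camera_paired_with_itself_gives_identity(self):
        rig = make_default_rig()
        obs_a, _ = _paired_views(rig, 0, 1, n_views=5, noise_px=0.0, seed=14)
        cam = rig.cameras[0]
        res = calibrate_stereo(
            BOARD, obs_a, obs_a,
            cam.intrinsics, cam.distortion, cam.intrinsics, cam.distortion,
        )
        assert rotation_angle_deg(res.transform.rotation) < 1e-8
        assert np.abs(res.transform.translation).max() < 1e-6

    def test_below_protocol_minimum_warns_but_succeeds(self, caplog):
        rig = make_default_rig()
        obs_a, obs_b = _paired_views(rig, 0, 1, n_views=10, noise_px=0.0, seed=15)
        cam_a, cam_b = rig.cameras[0], rig.cameras[1]
        with caplog.at_level(logging.WARNING, logger="hydromocap.calibration"):
            res = calibrate_stereo(
                BOARD, obs_a, obs_b,
                cam_a.intrinsics, cam_a.distortion, cam_b.intrinsics, cam_b.distortion,
            )
        assert res.n_views == 10
        assert any("protocol minimum" in rec.message for rec in caplog.records)

    def test_too_few_pairs_rejected(self):
        rig = make_default_rig()
        obs_a, obs_b = _paired_views(rig, 0, 1, n_views=2, noise_px=0.0, seed=16)
        cam_a, cam_b = rig.cameras[0], rig.cameras[1]
        with pytest.raises(ValueError, match=">= 3 paired views"):
            calibrate_stereo(
                BOARD, obs_a, obs_b,
                cam_a.intrinsics, cam_a.distortion, cam_b.intrinsics, cam_b.distortion,
            )
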