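"""Synthetic six-camera pool scene: the package's test universe.

Everything the pipeline consumes can be generated here with seeded noise:
a six-camera rig along one pool wall (composite field of view >= 2.6 m at
120 fps and 2.7K resolution), checkerboard sweeps for calibration and
error estimation, an articulated swimming limb driven by sinusoidal joint
trajectories, plumb-line/waterline markers defining the pool frame, and
luminance series with lighting-extinction events.

Ground truth is always emitted alongside the observations, and every
observation is the exact projection of ground truth before noise.  All
generators are deterministic given (parameters, seed).

The world frame of the rig coincides with the first camera's frame
("camera:cam1"): x to the right along the wall, y down, z toward the
swimming volume.  The pool-frame lateral axis (medio-lateral, pointing
from the swimming plane toward the cameras) is therefore -z in world
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .board_validation import REFERENCE_LABELS, CheckerboardModel, reference_geometry
from .calibration import BoardModel, BoardObservation
from .geometry import CameraModel, Distortion, Intrinsics, RigidTransform, project_valid
from .kinematics import AngleSeries, JointDefinition
from .reconstruction import GlobalFrameSpec, MarkerTrack2D, Trajectory3D
from .synchronization import LuminanceSeries

__all__ = [
    "RigSpec",
    "LimbModel",
    "JointTrajectory",
    "make_default_rig",
    "simulate_checkerboard_pass",
    "simulate_board_views",
    "simulate_swim",
    "simulate_plumb_and_waterline",
    "simulate_luminance",
    "default_front_limb",
    "default_hind_limb",
    "camera_frame_joint_definitions",
    "WORLD_FRAME",
    "CAMERA_FRAME_LATERAL_AXIS",
]

WORLD_FRAME = "camera:cam1"

#: the pool's medio-lateral direction expressed in the rig/world frame
CAMERA_FRAME_LATERAL_AXIS = (0.0, 0.0, -1.0)

_DEFAULT_IMAGE = (2704, 1520)


@dataclass
class RigSpec:
    """Six cameras along one pool wall, operated as three stereo pairs."""

    cameras: list[CameraModel]
    frame_rate: float = 120.0
    spacing_mm: float = 500.0
    distance_mm: float = 1300.0

    @property
    def pair_indices(self) -> list[tuple[int, int]]:
        return [(i, i + 1) for i in range(0, len(self.cameras) - 1, 2)]

    def camera(self, camera_id: str) -> CameraModel:
        for cam in self.cameras:
            if cam.camera_id == camera_id:
                return cam
        raise KeyError(camera_id)

    def stereo_transform(self, i: int, j: int) -> RigidTransform:
        """Ground-truth camera_i -> camera_j transform from the poses."""
        return self.cameras[i].pose.invert().compose(self.cameras[j].pose)


def make_default_rig(
    spacing_mm: float = 500.0,
    distance_mm: float = 1300.0,
    focal_px: float = 800.0,
    image_size: tuple[int, int] = _DEFAULT_IMAGE,
    distortion: Distortion = Distortion(k1=-0.25, k2=0.05),
    n_cameras: int = 6,
    frame_rate: float = 120.0,
    min_coverage_mm: float = 2600.0,
    min_overlap_fraction: float = 0.10,
) -> RigSpec:
    """The default six-camera rig.

    Cameras sit at equal spacing along the wall (world x axis), all facing
    the motion plane at ``distance_mm``.  Intrinsics default to a
    wide-angle 2.7K model (fx = fy = 800 px) whose composite horizontal
    coverage at the working distance exceeds 2.6 m with ample pairwise
    overlap; mild barrel distortion is on by default so undistortion is
    non-trivially exercised.
    """
    if spacing_mm <= 0 or distance_mm <= 0 or focal_px <= 0:
        raise ValueError("rig geometry parameters must be positive")
    width, height = image_size
    intr = Intrinsics(
        focal_px, focal_px, (width - 1) / 2.0, (height - 1) / 2.0,
        image_width=width, image_height=height,
    )
    cameras = []
    for i in range(n_cameras):
        cam_id = f"cam{i + 1}"
        pose = RigidTransform(
            np.eye(3),
            np.array([-i * spacing_mm, 0.0, 0.0]),
            source_frame=WORLD_FRAME,
            target_frame=f"camera:{cam_id}",
        )
        cameras.append(CameraModel(cam_id, intr, distortion, pose))

    half_left = intr.cx / intr.fx * distance_mm
    half_right = (width - 1 - intr.cx) / intr.fx * distance_mm
    coverage = (n_cameras - 1) * spacing_mm + half_left + half_right
    if coverage < min_coverage_mm:
        raise ValueError(
            f"composite coverage {coverage:.0f} mm below {min_coverage_mm:.0f} mm"
        )
    overlap = half_left + half_right - spacing_mm
    if overlap < min_overlap_fraction * (half_left + half_right):
        raise ValueError(
            f"adjacent cameras overlap by {overlap:.0f} mm, below "
            f"{min_overlap_fraction:.0%} of the per-camera coverage"
        )
    return RigSpec(cameras, frame_rate, spacing_mm, distance_mm)


# ---------------------------------------------------------------------------
# checkerboard sweep
# ---------------------------------------------------------------------------

def default_board() -> BoardModel:
    """9x7 interior corners at 60 mm pitch: the 600 x 480 mm validation board."""
    return BoardModel(n_rows=7, n_cols=9, square_size=60.0)


def _sweep_poses(
    n_frames: int,
    frame_rate: float,
    x_start: float,
    x_end: float,
    distance_mm: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth board path: rotations (T,3,3) and centers (T,3)."""
    t = np.arange(n_frames) / frame_rate
    duration = max(t[-1], 1e-9) if n_frames > 1 else 1.0
    centers = np.column_stack(
        [
            x_start + (x_end - x_start) * t / duration,
            150.0 * np.sin(2 * np.pi * 0.05 * t + 1.0),
            distance_mm + 200.0 * np.sin(2 * np.pi * 0.045 * t + 2.0),
        ]
    )
    # ample, incommensurate oscillations: every camera's window sees a
    # variety of board orientations, as the calibration protocol demands
    yaw = np.radians(35.0) * np.sin(2 * np.pi * 0.31 * t + 0.5)
    pitch = np.radians(25.0) * np.sin(2 * np.pi * 0.23 * t + 1.7)
    roll = np.radians(20.0) * np.sin(2 * np.pi * 0.17 * t + 2.9)
    rotations = Rotation.from_euler("yxz", np.column_stack([yaw, pitch, roll])).as_matrix()
    return rotations, centers


def simulate_checkerboard_pass(
    rig: RigSpec,
    board: BoardModel | None = None,
    model: CheckerboardModel | None = None,
    duration_s: float = 60.0,
    noise_px: float = 0.5,
    seed: int = 0,
    view_stride: int = 30,
    min_corners: int = 10,
) -> tuple[list[BoardObservation], list[MarkerTrack2D], dict[str, Trajectory3D]]:
    """Sweep the validation checkerboard across the whole rig.

    The board translates across the full composite field of view with
    smooth yaw/pitch/roll oscillations.  Grid corners are emitted as
    :class:`BoardObservation` every ``view_stride`` frames (calibration
    input); the five reference points are emitted as per-camera 2D tracks
    for every frame (validation input).  Pixels are perturbed by isotropic
    Gaussian noise of ``noise_px`` std; points behind a camera or outside
    its image are invisible.

    Returns ``(board_observations, reference_tracks, ground_truth)`` with
    ground-truth trajectories in the first camera's frame.
    """
    if noise_px < 0:
        raise ValueError("noise_px must be >= 0")
    board = board or default_board()
    model = model or reference_geometry()
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * rig.frame_rate))

    # board-frame points share the reference-geometry frame: the grid
    # corners of the 600x480 board start one square in from TL
    grid = board.corner_points() + np.array([board.square_size, board.square_size, 0.0])
    refs = model.point_array(REFERENCE_LABELS)
    board_pts = np.vstack([grid, refs])
    n_grid = len(grid)
    board_center = board_pts.mean(axis=0)

    # overshoot the rig ends so the outermost cameras also see the board
    # on both sides of their optical axis (balanced view geometry)
    n_cams = len(rig.cameras)
    x_min = -1200.0
    x_max = (n_cams - 1) * rig.spacing_mm + 1200.0
    rotations, centers = _sweep_poses(n_frames, rig.frame_rate, x_min, x_max, rig.distance_mm)
    world_pts = (
        np.einsum("tij,pj->tpi", rotations, board_pts - board_center)
        + centers[:, None, :]
    )

    observations: list[BoardObservation] = []
    tracks: list[MarkerTrack2D] = []
    view_frames = np.arange(0, n_frames, view_stride)
    any_seen = False
    for cam in rig.cameras:
        flat = world_pts.reshape(-1, 3)
        pix, vis = project_valid(flat, cam)
        pix = pix.reshape(n_frames, -1, 2)
        vis = vis.reshape(n_frames, -1)
        if noise_px > 0:
            pix = pix + rng.normal(0.0, noise_px, size=pix.shape)
        any_seen = any_seen or bool(vis.any())

        for f in view_frames:
            ids = np.flatnonzero(vis[f, :n_grid])
            if len(ids) >= min_corners:
                observations.append(
                    BoardObservation(f"v{f:06d}", cam.camera_id, ids, pix[f, ids])
                )
        for k, label in enumerate(REFERENCE_LABELS):
            col = n_grid + k
            frames = np.flatnonzero(vis[:, col])
            tracks.append(MarkerTrack2D(cam.camera_id, label, frames, pix[frames, col]))

    if not any_seen:
        raise ValueError("the board path never enters any camera's field of view")

    ground_truth = {
        label: Trajectory3D(
            label,
            np.arange(n_frames),
            world_pts[:, n_grid + k, :],
            WORLD_FRAME,
        )
        for k, label in enumerate(REFERENCE_LABELS)
    }
    return observations, tracks, ground_truth


def simulate_board_views(
    camera: CameraModel,
    board: BoardModel,
    n_views: int = 20,
    noise_px: float = 0.0,
    seed: int = 0,
    depth_range: tuple[float, float] = (900.0, 1800.0),
    tilt_deg: float = 45.0,
) -> tuple[list[BoardObservation], list[RigidTransform]]:
    """Random fully visible board views of a single camera.

    Convenience generator for intrinsic-calibration experiments: board
    poses with varied tilt (up to ``tilt_deg`` about both in-plane axes,
    defaulting to the ~45 degree inclination planar calibration guidance
    recommends) and full roll, placed so every corner lands inside the
    image.  Returns the observations and the ground-truth board->camera
    poses.
    """
    rng = np.random.default_rng(seed)
    pts = board.corner_points()
    center = pts.mean(axis=0)
    intr = camera.intrinsics
    observations, poses = [], []
    attempts = 0
    while len(observations) < n_views:
        attempts += 1
        if attempts > 200 * n_views:
            raise RuntimeError("could not place enough fully visible board views")
        angles = np.radians(
            [
                rng.uniform(-tilt_deg, tilt_deg),
                rng.uniform(-tilt_deg, tilt_deg),
                rng.uniform(-180.0, 180.0),
            ]
        )
        r = Rotation.from_euler("xyz", angles).as_matrix()
        depth = rng.uniform(*depth_range)
        # aim the board center at a random point in the central image region
        u = rng.uniform(0.25, 0.75) * intr.image_width
        v = rng.uniform(0.25, 0.75) * intr.image_height
        target = np.array(
            [(u - intr.cx) / intr.fx * depth, (v - intr.cy) / intr.fy * depth, depth]
        )
        t = target - r @ center
        cam_world = pts @ r.T + t  # already camera-frame: camera pose is identity here
        view_cam = CameraModel("view", intr, camera.distortion, RigidTransform.identity())
        pix, vis = project_valid(cam_world, view_cam)
        if not vis.all():
            continue
        if noise_px > 0:
            pix = pix + rng.normal(0.0, noise_px, size=pix.shape)
        vid = f"v{len(observations):04d}"
        observations.append(
            BoardObservation(vid, camera.camera_id, np.arange(len(pts)), pix)
        )
        poses.append(
            RigidTransform(r, t, source_frame="board", target_frame=f"camera:{camera.camera_id}")
        )
    return observations, poses


# ---------------------------------------------------------------------------
# articulated swimming limb
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JointTrajectory:
    """Sinusoidal prescription for one joint: angle(t) = mean + amp * sin(...)."""

    mean_deg: float
    amplitude_deg: float
    phase_rad: float = 0.0

    def angles(self, t: np.ndarray, period_s: float) -> np.ndarray:
        return self.mean_deg + self.amplitude_deg * np.sin(
            2 * np.pi * t / period_s + self.phase_rad
        )


@dataclass
class LimbModel:
    """An articulated limb: five segments, six markers, four driven joints.

    Segment lengths are in mm, ordered proximal to distal; joint
    trajectories are keyed by joint name in the same order (the joint
    between segment k and segment k+1).  The root angle describes the
    orientation of the proximal segment (degrees from straight down,
    positive toward the direction of travel).
    """

    name: str
    segment_lengths: tuple[float, ...]
    marker_labels: tuple[str, ...]
    joint_names: tuple[str, ...]
    joint_trajectories: dict[str, JointTrajectory]
    root_angle: JointTrajectory = field(
        default_factory=lambda: JointTrajectory(15.0, 10.0, 0.0)
    )

    def __post_init__(self):
        if len(self.marker_labels) != 6:
            raise ValueError("a limb carries exactly 6 markers")
        if any(l <= 0 for l in self.segment_lengths):
            raise ValueError("segment lengths must be positive")
        if len(self.segment_lengths) != 5 or len(self.joint_names) != 4:
            raise ValueError("expected 5 segments and 4 joints")


def default_front_limb() -> LimbModel:
    """Front limb: scapula / humerus / radius / metacarpus / front digit.

    Joint means and amplitudes follow the reported swim ranges (e.g.
    carpus mean 118.5 deg, amplitude 49.5 deg); the front fetlock
    hyperextends past 180 deg at peak extension.
    """
    return LimbModel(
        name="front",
        segment_lengths=(450.0, 330.0, 380.0, 250.0, 150.0),
        marker_labels=(
            "scapular_spine", "shoulder", "elbow", "carpus", "front_fetlock", "front_hoof",
        ),
        joint_names=("shoulder", "elbow", "carpus", "front_fetlock"),
        joint_trajectories={
            "shoulder": JointTrajectory(110.5, 8.5, 0.0),
            "elbow": JointTrajectory(95.5, 37.5, 0.6),
            "carpus": JointTrajectory(118.5, 49.5, 1.2),
            "front_fetlock": JointTrajectory(163.0, 34.0, 1.8),
        },
    )


def default_hind_limb() -> LimbModel:
    """Hind limb: ilium / femur / tibia / metatarsus / hind digit."""
    return LimbModel(
        name="hind",
        segment_lengths=(400.0, 420.0, 430.0, 290.0, 150.0),
        marker_labels=(
            "tuber_coxae", "hip", "stifle", "tarsus", "hind_fetlock", "hind_hoof",
        ),
        joint_names=("hip", "stifle", "tarsus", "hind_fetlock"),
        joint_trajectories={
            "hip": JointTrajectory(87.0, 19.5, 0.3),
            "stifle": JointTrajectory(112.0, 34.0, 0.9),
            "tarsus": JointTrajectory(112.0, 49.5, 1.5),
            "hind_fetlock": JointTrajectory(156.0, 47.0, 2.1),
        },
    )


def camera_frame_joint_definitions(definitions) -> tuple[JointDefinition, ...]:
    """Joint definitions with the lateral axis re-expressed in the rig frame."""
    return tuple(
        JointDefinition(
            jd.name, jd.proximal, jd.vertex, jd.distal,
            lateral_axis=CAMERA_FRAME_LATERAL_AXIS,
        )
        for jd in definitions
    )


def _rodrigues(axis: np.ndarray, angle_rad: float, v: np.ndarray) -> np.ndarray:
    return (
        v * np.cos(angle_rad)
        + np.cross(axis, v) * np.sin(angle_rad)
        + axis * np.dot(axis, v) * (1.0 - np.cos(angle_rad))
    )


def _limb_marker_positions(
    limb: LimbModel,
    t: np.ndarray,
    period_s: float,
    root_xy: np.ndarray,
    depth_mm: float,
    wobble_deg: float,
    wobble_phase: float,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Positions (per marker, (T,3)) and prescribed angles (per joint)."""
    n = len(t)
    angles = {
        name: limb.joint_trajectories[name].angles(t, period_s) for name in limb.joint_names
    }
    root = limb.root_angle.angles(t, period_s)
    wobble = np.radians(wobble_deg) * np.sin(2 * np.pi * t / period_s + wobble_phase)

    positions = {lbl: np.zeros((n, 3)) for lbl in limb.marker_labels}
    base_lateral = np.array([0.0, 0.0, -1.0])
    advance_axis = np.array([1.0, 0.0, 0.0])
    down = np.array([0.0, 1.0, 0.0])
    for i in range(n):
        # lateral axis wobbles about the direction of travel to exercise
        # genuinely 3D geometry; the chain lives in the plane normal to it
        lateral = _rodrigues(advance_axis, wobble[i], base_lateral)
        d = _rodrigues(lateral, np.radians(root[i]), down)
        d -= lateral * np.dot(lateral, d)
        d /= np.linalg.norm(d)
        p = np.array([root_xy[i, 0], root_xy[i, 1], depth_mm])
        positions[limb.marker_labels[0]][i] = p
        for k, seg_len in enumerate(limb.segment_lengths):
            p = p + seg_len * d
            positions[limb.marker_labels[k + 1]][i] = p
            if k < len(limb.joint_names):
                theta = np.radians(angles[limb.joint_names[k]][i])
                d = _rodrigues(lateral, theta, -d)
    return positions, angles


def simulate_swim(
    rig: RigSpec,
    front: LimbModel | None = None,
    hind: LimbModel | None = None,
    n_cycles: int = 2,
    cycle_duration_s: float = 1.5,
    noise_px: float = 0.5,
    seed: int = 0,
    wobble_deg: float = 5.0,
    bob_amplitude_mm: float = 50.0,
) -> tuple[list[MarkerTrack2D], dict[str, AngleSeries], dict[str, Trajectory3D]]:
    """Animate a swimming horse's limbs across the rig.

    Both limbs are planar-dominant kinematic chains driven by sinusoidal
    joint trajectories with the reported swim means/amplitudes and a
    ~1.5 s cycle, plus a small out-of-plane wobble.  The horse advances at
    constant speed across the 2.6 m window with a gentle vertical bob.
    Observations are projected through every camera and perturbed with
    Gaussian pixel noise.

    Returns ``(tracks, ground_truth_angles, ground_truth_trajectories)``;
    trajectories are in the first camera's frame and the angle series are
    the exact prescriptions.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    front = front or default_front_limb()
    hind = hind or default_hind_limb()
    rng = np.random.default_rng(seed)
    duration = n_cycles * cycle_duration_s
    n_frames = int(round(duration * rig.frame_rate))
    t = np.arange(n_frames) / rig.frame_rate

    span = (len(rig.cameras) - 1) * rig.spacing_mm
    x_front = 0.2 * span + (0.9 - 0.2) * span * t / duration + 1300.0
    y_root = -450.0 + bob_amplitude_mm * np.sin(2 * np.pi * t / cycle_duration_s)
    root_front = np.column_stack([x_front, y_root])
    root_hind = np.column_stack([x_front - 1300.0, y_root + 30.0])

    positions: dict[str, np.ndarray] = {}
    truth_angles: dict[str, np.ndarray] = {}
    for limb, root_xy, phase in ((front, root_front, 0.0), (hind, root_hind, np.pi / 3)):
        pos, ang = _limb_marker_positions(
            limb, t, cycle_duration_s, root_xy, rig.distance_mm, wobble_deg, phase
        )
        positions.update(pos)
        truth_angles.update(ang)

    labels = list(positions)
    all_pts = np.stack([positions[lbl] for lbl in labels], axis=1)  # (T, L, 3)

    tracks: list[MarkerTrack2D] = []
    n_visible_total = 0
    for cam in rig.cameras:
        pix, vis = project_valid(all_pts.reshape(-1, 3), cam)
        pix = pix.reshape(n_frames, -1, 2)
        vis = vis.reshape(n_frames, -1)
        if noise_px > 0:
            pix = pix + rng.normal(0.0, noise_px, size=pix.shape)
        n_visible_total += int(vis.sum())
        for k, label in enumerate(labels):
            frames = np.flatnonzero(vis[:, k])
            tracks.append(MarkerTrack2D(cam.camera_id, label, frames, pix[frames, k]))
    if n_visible_total == 0:
        import logging

        logging.getLogger(__name__).warning("the limb never enters any field of view")

    angle_series = {
        name: AngleSeries(name, np.arange(n_frames), vals, rig.frame_rate)
        for name, vals in truth_angles.items()
    }
    trajectories = {
        lbl: Trajectory3D(lbl, np.arange(n_frames), positions[lbl], WORLD_FRAME)
        for lbl in labels
    }
    return tracks, angle_series, trajectories


# ---------------------------------------------------------------------------
# pool frame and synchronization inputs
# ---------------------------------------------------------------------------

def default_pool_pose() -> RigidTransform:
    """Default camera-1 -> pool transform used by the generators.

    Pool axes in rig coordinates: z up = -y, y along the wall = +x, and x
    (medio-lateral, toward the cameras) = -z; origin at the first plumb
    ball.
    """
    rotation = np.array([[0.0, 0.0, -1.0], [1.0, 0.0, 0.0], [0.0, -1.0, 0.0]])
    ball = np.array([100.0, -900.0, 1250.0])
    return RigidTransform(
        rotation, -rotation @ ball, source_frame=WORLD_FRAME, target_frame="pool"
    )


def simulate_plumb_and_waterline(
    rig: RigSpec, pool_pose: RigidTransform | None = None
) -> tuple[GlobalFrameSpec, RigidTransform]:
    """Plumb-line and waterline markers expressed in camera-1 coordinates.

    Two weighted vertical lines (fluorescent ball above, fishing weight
    below) define the vertical; three foam delineators on the water
    surface define the horizontal.  Returns the marker spec together with
    the planted camera-1 -> pool ground-truth transform (whose origin is
    the first plumb ball).
    """
    pose = pool_pose or default_pool_pose()
    to_cam = pose.invert()
    # canonical pool-frame layout: first ball at the pool origin
    line1 = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, -900.0]])
    line2 = np.array([[0.0, 1600.0, 0.0], [0.0, 1600.0, -900.0]])
    waterline = np.array([[0.0, 0.0, 380.0], [0.0, 800.0, 380.0], [0.0, 1600.0, 380.0]])
    spec = GlobalFrameSpec(
        plumb_lines=[to_cam.apply(line1), to_cam.apply(line2)],
        waterline_points=to_cam.apply(waterline),
        coordinate_frame=pose.source_frame,
    )
    return spec, pose


def simulate_luminance(
    camera_ids: list[str],
    offsets: dict[str, int] | None = None,
    event_frames: tuple[int, ...] = (240, 330, 420, 1230),
    n_frames: int = 1440,
    dip_frames: int = 12,
    dip_level: float = 0.05,
    noise: float = 0.0,
    seed: int = 0,
) -> list[LuminanceSeries]:
    """Luminance series with square lighting-extinction dips.

    The default schedule plants three dips before the recorded event and
    one after.  Each camera's series is shifted by its integer offset
    (the dip at frame e appears at e + offset in that camera's clock) and
    optionally perturbed by Gaussian noise.
    """
    offsets = offsets or {}
    rng = np.random.default_rng(seed)
    out = []
    for cam_id in camera_ids:
        off = int(offsets.get(cam_id, 0))
        lum = np.ones(n_frames)
        for e in event_frames:
            start = e + off
            if 0 <= start < n_frames:
                lum[start : min(start + dip_frames, n_frames)] = dip_level
        if noise > 0:
            lum = lum + rng.normal(0.0, noise, size=n_frames)
        out.append(LuminanceSeries(cam_id, lum, 120.0))
    return out
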