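"""Stereo 3D reconstruction: DLT triangulation, frame unification, pool frame.

The rig is operated as three independent stereo pairs (cameras 1-2, 3-4,
5-6).  Each pair triangulates markers into the local frame of its first
camera.  Because adjacent pairs overlap in their fields of view, the same
marker samples are reconstructed by both, and a least-squares rigid fit
("transition matrix") between the duplicated samples chains every
pair-local frame into the frame of the first camera.  A final rigid
transform built from plumb-line and waterline markers maps everything into
the global pool frame (z up, y horizontal along the waterline, x
completing the right-handed trihedron).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import CameraModel, RigidTransform, undistort_pixel

__all__ = [
    "MarkerTrack2D",
    "Trajectory3D",
    "GlobalFrameSpec",
    "TriangulationResult",
    "triangulate_dlt",
    "triangulate_dlt_batch",
    "reconstruct_pair",
    "estimate_transition",
    "unify_frames",
    "build_global_frame",
    "interpolate_gaps",
    "undistort_tracks",
]

logger = logging.getLogger(__name__)

#: triangulations with reprojection residual above this many pixels are flagged
DEFAULT_RESIDUAL_GATE_PX = 5.0


@dataclass
class MarkerTrack2D:
    """Frame-indexed 2D observations of one labelled marker in one camera.

    Only visible samples are stored; a frame absent from ``frames`` is
    invisible.  Frame indices are 0-based and strictly increasing.
    """

    camera_id: str
    label: str
    frames: np.ndarray  # (N,) int
    pixels: np.ndarray  # (N, 2) float

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int).reshape(-1)
        self.pixels = np.asarray(self.pixels, dtype=float).reshape(-1, 2)
        if len(self.frames) != len(self.pixels):
            raise ValueError("frames and pixels length mismatch")
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError(f"frame indices must be strictly increasing ({self.label})")


@dataclass
class Trajectory3D:
    """Frame-indexed reconstructed 3D points (mm) with an explicit frame tag."""

    label: str
    frames: np.ndarray  # (N,) int
    points: np.ndarray  # (N, 3) float mm
    coordinate_frame: str

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int).reshape(-1)
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.frames) != len(self.points):
            raise ValueError("frames and points length mismatch")
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError(f"frame indices must be strictly increasing ({self.label})")
        if np.isnan(self.points).any():
            raise ValueError(f"NaN coordinates in visible frames of {self.label!r}")

    def transformed(self, transform: RigidTransform) -> "Trajectory3D":
        if transform.source_frame != self.coordinate_frame:
            raise ValueError(
                f"trajectory is in frame {self.coordinate_frame!r} but transform "
                f"maps from {transform.source_frame!r}"
            )
        return Trajectory3D(
            label=self.label,
            frames=self.frames.copy(),
            points=transform.apply(self.points),
            coordinate_frame=transform.target_frame,
        )


@dataclass
class GlobalFrameSpec:
    """Markers defining the pool frame, expressed in the camera-1 frame.

    ``plumb_lines``: one (M >= 2, 3) array per weighted vertical line,
    ordered ball (top) to weight (bottom) — the ball-to-weight direction is
    -z.  ``waterline_points``: (K >= 2, 3) foam delineators on the water
    surface.  The pool origin is the first point of the first plumb line.
    """

    plumb_lines: list[np.ndarray]
    waterline_points: np.ndarray
    coordinate_frame: str = "camera:cam1"

    def __post_init__(self):
        self.plumb_lines = [np.asarray(p, dtype=float).reshape(-1, 3) for p in self.plumb_lines]
        if not self.plumb_lines or any(len(p) < 2 for p in self.plumb_lines):
            raise ValueError("each plumb line needs >= 2 points")
        self.waterline_points = np.asarray(self.waterline_points, dtype=float).reshape(-1, 3)
        if len(self.waterline_points) < 2:
            raise ValueError(">= 2 waterline points required")


@dataclass
class TriangulationResult:
    point: np.ndarray  # (3,) mm
    residuals: tuple[float, float]  # reprojection residual per camera, px
    flagged: bool = False
    reason: str | None = None


def triangulate_dlt(
    pixel_a: np.ndarray,
    pixel_b: np.ndarray,
    proj_a: np.ndarray,
    proj_b: np.ndarray,
    residual_gate_px: float = DEFAULT_RESIDUAL_GATE_PX,
) -> TriangulationResult:
    """Triangulate one point from two undistorted pixel observations.

    Solves the stacked homogeneous 4x4 DLT system by the smallest singular
    vector and dehomogenizes.  A near-zero homogeneous w raises (point at
    infinity).  High reprojection residuals or negative depths flag the
    result without dropping it.
    """
    pts, res, flags, reasons = triangulate_dlt_batch(
        np.asarray(pixel_a, dtype=float).reshape(1, 2),
        np.asarray(pixel_b, dtype=float).reshape(1, 2),
        proj_a,
        proj_b,
        residual_gate_px,
    )
    return TriangulationResult(
        point=pts[0],
        residuals=(float(res[0, 0]), float(res[0, 1])),
        flagged=bool(flags[0]),
        reason=reasons[0],
    )


def triangulate_dlt_batch(
    pixels_a: np.ndarray,
    pixels_b: np.ndarray,
    proj_a: np.ndarray,
    proj_b: np.ndarray,
    residual_gate_px: float = DEFAULT_RESIDUAL_GATE_PX,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Vectorized two-view DLT for (N, 2) pixel arrays.

    Returns ``(points (N,3), residuals (N,2), flagged (N,), reasons)``.
    """
    pixels_a = np.asarray(pixels_a, dtype=float).reshape(-1, 2)
    pixels_b = np.asarray(pixels_b, dtype=float).reshape(-1, 2)
    n = len(pixels_a)
    if len(pixels_b) != n:
        raise ValueError("pixel arrays length mismatch")

    a = np.empty((n, 4, 4))
    a[:, 0] = pixels_a[:, 0, None] * proj_a[2] - proj_a[0]
    a[:, 1] = pixels_a[:, 1, None] * proj_a[2] - proj_a[1]
    a[:, 2] = pixels_b[:, 0, None] * proj_b[2] - proj_b[0]
    a[:, 3] = pixels_b[:, 1, None] * proj_b[2] - proj_b[1]
    _, _, vt = np.linalg.svd(a)
    hom = vt[:, -1, :]  # (N, 4)
    w = hom[:, 3]
    if np.any(np.abs(w) < 1e-12):
        raise ValueError("triangulated point at infinity (|w| < 1e-12)")
    points = hom[:, :3] / w[:, None]

    residuals = np.empty((n, 2))
    depths = np.empty((n, 2))
    for j, (proj, pix) in enumerate(((proj_a, pixels_a), (proj_b, pixels_b))):
        ph = points @ proj[:, :3].T + proj[:, 3]
        depths[:, j] = ph[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            reproj = ph[:, :2] / ph[:, 2:3]
        residuals[:, j] = np.linalg.norm(reproj - pix, axis=1)

    flagged = np.zeros(n, dtype=bool)
    reasons: list = [None] * n
    behind = (depths <= 0).any(axis=1)
    high = np.nan_to_num(residuals, nan=np.inf).max(axis=1) > residual_gate_px
    for i in np.flatnonzero(behind):
        flagged[i], reasons[i] = True, "negative depth"
    for i in np.flatnonzero(high & ~behind):
        flagged[i], reasons[i] = True, f"residual above {residual_gate_px} px"
    return points, residuals, flagged, reasons


def reconstruct_pair(
    tracks_a: list[MarkerTrack2D],
    tracks_b: list[MarkerTrack2D],
    camera_a: CameraModel,
    camera_b: CameraModel,
    stereo: RigidTransform,
    residual_gate_px: float = DEFAULT_RESIDUAL_GATE_PX,
) -> dict[str, Trajectory3D]:
    """Triangulate every label of one camera pair into the first camera's frame.

    Tracks must already be synchronized and undistorted.  Only frames in
    which both cameras see a label are reconstructed; a label with no
    common visible frame yields an empty trajectory (with a warning).
    ``stereo`` maps camera_a -> camera_b coordinates.
    """
    frame_tag = f"camera:{camera_a.camera_id}"
    proj_a = camera_a.intrinsics.matrix @ np.hstack([np.eye(3), np.zeros((3, 1))])
    proj_b = camera_b.intrinsics.matrix @ np.hstack(
        [stereo.rotation, stereo.translation[:, None]]
    )
    by_label_a = {t.label: t for t in tracks_a}
    by_label_b = {t.label: t for t in tracks_b}

    out: dict[str, Trajectory3D] = {}
    for label in sorted(set(by_label_a) & set(by_label_b)):
        ta, tb = by_label_a[label], by_label_b[label]
        common, ia, ib = np.intersect1d(ta.frames, tb.frames, return_indices=True)
        if len(common) == 0:
            logger.warning(
                "label %r has no common visible frames in pair (%s, %s)",
                label, camera_a.camera_id, camera_b.camera_id,
            )
            out[label] = Trajectory3D(label, np.empty(0, int), np.empty((0, 3)), frame_tag)
            continue
        points, _, flagged, _ = triangulate_dlt_batch(
            ta.pixels[ia], tb.pixels[ib], proj_a, proj_b, residual_gate_px
        )
        if flagged.any():
            logger.warning(
                "pair (%s, %s) label %r: %d/%d triangulations flagged",
                camera_a.camera_id, camera_b.camera_id, label,
                int(flagged.sum()), len(flagged),
            )
        out[label] = Trajectory3D(label, common, points, frame_tag)
    return out


def undistort_tracks(tracks: list[MarkerTrack2D], cameras: dict[str, CameraModel]) -> list[MarkerTrack2D]:
    """Replace raw pixel observations by their ideal-pinhole positions."""
    out = []
    for t in tracks:
        cam = cameras[t.camera_id]
        pixels = (
            undistort_pixel(t.pixels, cam.intrinsics, cam.distortion)
            if len(t.pixels)
            else t.pixels
        )
        out.append(MarkerTrack2D(t.camera_id, t.label, t.frames.copy(), pixels))
    return out


def estimate_transition(
    points_a: np.ndarray,
    points_b: np.ndarray,
    source_frame: str = "a",
    target_frame: str = "b",
) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit mapping point set a onto point set b.

    Cross-covariance singular decomposition with determinant sign
    correction (no scale factor).  Returns the proper rigid transform and
    the RMS residual in mm.  Fewer than 3 points, or a collinear set,
    raise an error.
    """
    points_a = np.asarray(points_a, dtype=float).reshape(-1, 3)
    points_b = np.asarray(points_b, dtype=float).reshape(-1, 3)
    if len(points_a) != len(points_b):
        raise ValueError("point sets must have equal length")
    if len(points_a) < 3:
        raise ValueError(f"transition estimation needs >= 3 correspondences, got {len(points_a)}")
    ca, cb = points_a.mean(axis=0), points_b.mean(axis=0)
    da, db = points_a - ca, points_b - cb
    # collinearity check on the source set
    s_src = np.linalg.svd(da, compute_uv=False)
    if s_src[1] < 1e-9 * max(s_src[0], 1.0):
        raise ValueError("point set is collinear; the rigid fit is under-determined")
    h = da.T @ db
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = cb - rotation @ ca
    transform = RigidTransform(rotation, translation, source_frame, target_frame)
    rms = float(np.sqrt(np.mean(np.sum((transform.apply(points_a) - points_b) ** 2, axis=1))))
    return transform, rms


def _shared_samples(
    trajs_a: dict[str, Trajectory3D], trajs_b: dict[str, Trajectory3D]
) -> tuple[np.ndarray, np.ndarray]:
    pa, pb = [], []
    for label in set(trajs_a) & set(trajs_b):
        ta, tb = trajs_a[label], trajs_b[label]
        _, ia, ib = np.intersect1d(ta.frames, tb.frames, return_indices=True)
        pa.append(ta.points[ia])
        pb.append(tb.points[ib])
    if not pa:
        return np.empty((0, 3)), np.empty((0, 3))
    return np.vstack(pa), np.vstack(pb)


def unify_frames(
    pair_trajectories: list[dict[str, Trajectory3D]],
    min_overlap: int = 3,
) -> dict[str, Trajectory3D]:
    """Merge per-pair reconstructions into the first pair's frame.

    ``pair_trajectories`` is ordered along the rig (pair 1-2 first).  For
    each adjacent pair the rigid transition is estimated from all (label,
    frame) samples reconstructed by both, then chained by composition back
    to the first pair's frame.  Samples reconstructed by several pairs are
    merged by unweighted averaging after transformation.
    """
    if not pair_trajectories:
        raise ValueError("no pair trajectories given")
    if len(pair_trajectories) == 1:
        return dict(pair_trajectories[0])
    target_frame = next(iter(pair_trajectories[0].values())).coordinate_frame

    transformed: list[dict[str, Trajectory3D]] = [dict(pair_trajectories[0])]
    to_first: RigidTransform | None = None  # current pair frame -> first pair frame
    for k in range(1, len(pair_trajectories)):
        prev, cur = pair_trajectories[k - 1], pair_trajectories[k]
        pts_cur, pts_prev = _shared_samples(cur, prev)
        if len(pts_cur) < min_overlap:
            raise ValueError(
                f"pairs {k} and {k + 1} share only {len(pts_cur)} reconstructed "
                f"samples (need >= {min_overlap}); cannot estimate the transition"
            )
        cur_frame = next(iter(cur.values())).coordinate_frame
        prev_frame = next(iter(prev.values())).coordinate_frame
        step, rms = estimate_transition(pts_cur, pts_prev, cur_frame, prev_frame)
        logger.info(
            "transition %s -> %s from %d overlap samples (RMS %.3f mm)",
            cur_frame, prev_frame, len(pts_cur), rms,
        )
        to_first = step if to_first is None else step.compose(to_first)
        transformed.append({lbl: t.transformed(to_first) for lbl, t in cur.items()})

    # merge duplicated (label, frame) samples by unweighted averaging
    out: dict[str, Trajectory3D] = {}
    labels = sorted({lbl for trajs in transformed for lbl in trajs})
    for label in labels:
        acc: dict[int, list[np.ndarray]] = {}
        for trajs in transformed:
            t = trajs.get(label)
            if t is None:
                continue
            for f, p in zip(t.frames, t.points):
                acc.setdefault(int(f), []).append(p)
        frames = np.array(sorted(acc), dtype=int)
        points = np.array([np.mean(acc[f], axis=0) for f in frames]).reshape(-1, 3)
        out[label] = Trajectory3D(label, frames, points, target_frame)
    return out


def build_global_frame(
    spec: GlobalFrameSpec, min_angle_deg: float = 5.0, pool_frame: str = "pool"
) -> RigidTransform:
    """Rigid transform camera-1 frame -> pool frame.

    z is the unit up vector along the plumb lines (ball minus weight), y
    the waterline direction orthogonalized against z, and x = y cross z
    completes the right-handed trihedron.  The origin is the first plumb
    point.  Plumb and waterline directions within ``min_angle_deg`` of
    parallel are rejected.
    """
    ups = []
    for line in spec.plumb_lines:
        d = line[0] - line[-1]  # ball (top) minus weight (bottom) = up
        norm = np.linalg.norm(d)
        if norm < 1e-9:
            raise ValueError("degenerate plumb line (coincident points)")
        ups.append(d / norm)
    z = np.mean(ups, axis=0)
    z = z / np.linalg.norm(z)

    w = spec.waterline_points[-1] - spec.waterline_points[0]
    wn = np.linalg.norm(w)
    if wn < 1e-9:
        raise ValueError("degenerate waterline (coincident points)")
    w = w / wn
    if np.degrees(np.arcsin(np.clip(np.linalg.norm(np.cross(w, z)), 0.0, 1.0))) < min_angle_deg:
        raise ValueError(
            f"plumb and waterline directions are within {min_angle_deg} deg of parallel"
        )
    y = w - np.dot(w, z) * z
    y = y / np.linalg.norm(y)
    x = np.cross(y, z)
    rotation = np.vstack([x, y, z])  # rows: pool axes in camera-1 coordinates
    origin = spec.plumb_lines[0][0]
    return RigidTransform(
        rotation,
        -rotation @ origin,
        source_frame=spec.coordinate_frame,
        target_frame=pool_frame,
    )


def interpolate_gaps(trajectory: Trajectory3D, max_gap_frames: int = 12) -> Trajectory3D:
    """Fill missing frames by linear interpolation across short gaps.

    Runs of consecutive missing frames of length <= ``max_gap_frames``
    (default 12, about 0.1 s at 120 fps) are linearly interpolated; longer
    gaps are left missing.
    """
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be >= 0")
    f = trajectory.frames
    if len(f) < 2 or max_gap_frames == 0:
        return trajectory
    frames_out = [f[0]]
    points_out = [trajectory.points[0]]
    for i in range(1, len(f)):
        gap = f[i] - f[i - 1] - 1
        if 0 < gap <= max_gap_frames:
            alphas = np.arange(1, gap + 1) / (gap + 1)
            interp = (
                trajectory.points[i - 1][None, :] * (1 - alphas[:, None])
                + trajectory.points[i][None, :] * alphas[:, None]
            )
            frames_out.extend(range(f[i - 1] + 1, f[i]))
            points_out.extend(interp)
        frames_out.append(f[i])
        points_out.append(trajectory.points[i])
    return Trajectory3D(
        trajectory.label,
        np.asarray(frames_out, dtype=int),
        np.asarray(points_out),
        trajectory.coordinate_frame,
    )
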