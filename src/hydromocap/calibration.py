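"""Planar checkerboard calibration: intrinsics, board pose, and stereo pairs.

Single-camera calibration follows the classical planar approach: a
homography is estimated for every board view, the image of the absolute
conic yields closed-form intrinsics, and a damped least-squares refinement
then jointly optimizes intrinsics, Brown-Conrady distortion and per-view
poses against total reprojection error.

Stereo (pairwise extrinsic) calibration composes per-view board poses from
the two cameras into per-view relative poses, robustly averages them
(quaternion mean for rotation, componentwise median for translation), and
jointly refines the relative pose and board poses against reprojection
error in both cameras.

Corner detection from images is not implemented; observations arrive as
pixel lists (from the synthetic module or an external detector).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .geometry import (
    CameraModel,
    Distortion,
    Intrinsics,
    RigidTransform,
    rotation_angle_deg,
    undistort_pixel,
)

__all__ = [
    "BoardModel",
    "BoardObservation",
    "IntrinsicCalibrationResult",
    "StereoCalibrationResult",
    "DegenerateConfigurationError",
    "estimate_homography",
    "calibrate_intrinsics",
    "estimate_board_pose",
    "calibrate_stereo",
    "MIN_STEREO_PAIRS",
]

logger = logging.getLogger(__name__)

#: protocol minimum number of paired views for stereo calibration; fewer
#: views produce a warning, not an error.
MIN_STEREO_PAIRS = 15

_REFINE_TOL = 1e-12
_REFINE_MAX_ITER = 200


class DegenerateConfigurationError(ValueError):
    """Point/view configuration too degenerate to calibrate from."""


@dataclass(frozen=True)
class BoardModel:
    """An asymmetric planar checkerboard: interior-corner grid, z = 0.

    ``n_rows`` x ``n_cols`` interior corners with ``square_size`` mm pitch.
    The grid must be asymmetric (n_rows != n_cols) so board orientation is
    unambiguous.
    """

    n_rows: int
    n_cols: int
    square_size: float

    def __post_init__(self):
        if self.n_rows == self.n_cols:
            raise ValueError(
                f"checkerboard must be asymmetric: n_rows ({self.n_rows}) == n_cols"
            )
        if self.square_size <= 0:
            raise ValueError("square_size must be positive")

    @property
    def n_corners(self) -> int:
        return self.n_rows * self.n_cols

    def corner_points(self) -> np.ndarray:
        """(n_corners, 3) board-frame coordinates, z = 0, row-major order."""
        jj, ii = np.meshgrid(np.arange(self.n_cols), np.arange(self.n_rows))
        pts = np.zeros((self.n_corners, 3))
        pts[:, 0] = jj.ravel() * self.square_size
        pts[:, 1] = ii.ravel() * self.square_size
        return pts


@dataclass
class BoardObservation:
    """Detected corners of one board view seen by one camera."""

    view_id: str
    camera_id: str
    corner_ids: np.ndarray  # (N,) int indices into BoardModel.corner_points()
    pixels: np.ndarray  # (N, 2) raw (distorted) pixel coordinates

    def __post_init__(self):
        self.corner_ids = np.asarray(self.corner_ids, dtype=int).reshape(-1)
        self.pixels = np.asarray(self.pixels, dtype=float).reshape(-1, 2)
        if len(self.corner_ids) != len(self.pixels):
            raise ValueError("corner_ids and pixels length mismatch")
        if len(np.unique(self.corner_ids)) != len(self.corner_ids):
            raise ValueError(f"duplicate corner_ids in view {self.view_id!r}")


# ---------------------------------------------------------------------------
# homography
# ---------------------------------------------------------------------------

def _normalization_transform(points: np.ndarray) -> np.ndarray:
    """Similarity transform bringing points to centroid 0, RMS distance sqrt(2)."""
    centroid = points.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum((points - centroid) ** 2, axis=1)))
    if rms < 1e-12:
        raise DegenerateConfigurationError("all points coincide")
    s = np.sqrt(2.0) / rms
    return np.array([[s, 0, -s * centroid[0]], [0, s, -s * centroid[1]], [0, 0, 1]])


def estimate_homography(plane_points: np.ndarray, pixels: np.ndarray) -> np.ndarray:
    """Estimate the 3x3 homography mapping planar points (mm) to pixels.

    Normalized direct linear estimate minimizing algebraic error; the
    result is scaled so the bottom-right entry is 1 when nonzero.  Needs at
    least four non-collinear correspondences.
    """
    plane_points = np.asarray(plane_points, dtype=float).reshape(-1, 2)
    pixels = np.asarray(pixels, dtype=float).reshape(-1, 2)
    n = len(plane_points)
    if n != len(pixels):
        raise ValueError("point count mismatch")
    if n < 4:
        raise DegenerateConfigurationError(f"homography needs >= 4 correspondences, got {n}")

    t_src = _normalization_transform(plane_points)
    t_dst = _normalization_transform(pixels)
    src = plane_points @ t_src[:2, :2].T + t_src[:2, 2]
    dst = pixels @ t_dst[:2, :2].T + t_dst[:2, 2]

    a = np.zeros((2 * n, 9))
    x, y = src[:, 0], src[:, 1]
    u, v = dst[:, 0], dst[:, 1]
    a[0::2, 0] = -x
    a[0::2, 1] = -y
    a[0::2, 2] = -1.0
    a[0::2, 6] = u * x
    a[0::2, 7] = u * y
    a[0::2, 8] = u
    a[1::2, 3] = -x
    a[1::2, 4] = -y
    a[1::2, 5] = -1.0
    a[1::2, 6] = v * x
    a[1::2, 7] = v * y
    a[1::2, 8] = v
    _, s, vt = np.linalg.svd(a)
    if s[-2] < 1e-10 * s[0]:
        raise DegenerateConfigurationError("degenerate (collinear) point configuration")
    h = vt[-1].reshape(3, 3)
    h = np.linalg.inv(t_dst) @ h @ t_src
    if abs(h[2, 2]) > 1e-12:
        h = h / h[2, 2]
    return h


# ---------------------------------------------------------------------------
# closed-form intrinsics (image of the absolute conic)
# ---------------------------------------------------------------------------

def _vij(h: np.ndarray, i: int, j: int) -> np.ndarray:
    return np.array(
        [
            h[0, i] * h[0, j],
            h[0, i] * h[1, j] + h[1, i] * h[0, j],
            h[1, i] * h[1, j],
            h[2, i] * h[0, j] + h[0, i] * h[2, j],
            h[2, i] * h[1, j] + h[1, i] * h[2, j],
            h[2, i] * h[2, j],
        ]
    )


def _intrinsics_from_homographies(
    homographies: list[np.ndarray], image_size: tuple[int, int]
) -> Intrinsics | None:
    v = []
    for h in homographies:
        v.append(_vij(h, 0, 1))
        v.append(_vij(h, 0, 0) - _vij(h, 1, 1))
    v = np.asarray(v)
    _, _, vt = np.linalg.svd(v)
    b11, b12, b22, b13, b23, b33 = vt[-1]

    denom = b11 * b22 - b12 * b12
    with np.errstate(divide="ignore", invalid="ignore"):
        v0 = (b12 * b13 - b11 * b23) / denom
        lam = b33 - (b13 * b13 + v0 * (b12 * b13 - b11 * b23)) / b11
        alpha2 = lam / b11
        beta2 = lam * b11 / denom
    width, height = image_size
    if not (np.isfinite(alpha2) and np.isfinite(beta2)) or alpha2 <= 0 or beta2 <= 0:
        return None
    alpha = float(np.sqrt(alpha2))
    beta = float(np.sqrt(beta2))
    gamma = float(-b12 * alpha2 * beta / lam)
    u0 = float(gamma * v0 / beta - b13 * alpha2 / lam)
    # distortion-corrupted homographies can yield wild conic estimates;
    # the caller falls back to multi-start initialization in that case
    if not (0 < u0 < width and 0 < v0 < height) or not (
        0.1 * width < alpha < 5 * width and 0.1 * width < beta < 5 * width
    ):
        return None
    return Intrinsics(alpha, beta, u0, float(v0), gamma, width, height)


def _pose_from_homography(h: np.ndarray, k: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Initial board->camera pose (R, t) from a plane homography."""
    m = np.linalg.inv(k) @ h
    lam = 1.0 / np.linalg.norm(m[:, 0])
    # board should be in front of the camera
    if m[2, 2] * lam < 0:
        lam = -lam
    r1 = lam * m[:, 0]
    r2 = lam * m[:, 1]
    t = lam * m[:, 2]
    r = np.column_stack([r1, r2, np.cross(r1, r2)])
    u, _, vt = np.linalg.svd(r)
    r = u @ np.diag([1.0, 1.0, np.sign(np.linalg.det(u @ vt))]) @ vt
    return r, t


# ---------------------------------------------------------------------------
# reprojection machinery
# ---------------------------------------------------------------------------

def _distorted_pixels(
    cam: np.ndarray, intr_params: np.ndarray, dist_params: np.ndarray
) -> np.ndarray:
    """Camera-frame points -> distorted pixels (vectorized forward model)."""
    xy = cam[:, :2] / cam[:, 2:3]
    k1, k2, k3, p1, p2 = dist_params
    x, y = xy[:, 0], xy[:, 1]
    r2 = x * x + y * y
    radial = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
    xd = x * radial + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
    yd = y * radial + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
    fx, fy, cx, cy, skew = intr_params
    return np.column_stack([fx * xd + skew * yd + cx, fy * yd + cy])


def _project_board(
    board_pts: np.ndarray,
    rvec: np.ndarray,
    tvec: np.ndarray,
    intr_params: np.ndarray,
    dist_params: np.ndarray,
) -> np.ndarray:
    """Forward model: board-frame points -> distorted pixels."""
    r = Rotation.from_rotvec(rvec).as_matrix()
    return _distorted_pixels(board_pts @ r.T + tvec, intr_params, dist_params)


def _reprojection_rmse(residuals: np.ndarray) -> float:
    """RMS error per residual component (pixel coordinates, not 2D points)."""
    return float(np.sqrt(np.mean(residuals**2)))


@dataclass
class IntrinsicCalibrationResult:
    intrinsics: Intrinsics
    distortion: Distortion
    view_poses: dict[str, RigidTransform] = field(default_factory=dict)
    rmse_px: float = 0.0
    n_views: int = 0


@dataclass
class StereoCalibrationResult:
    transform: RigidTransform  # camera_a -> camera_b
    rmse_px: float = 0.0
    n_views: int = 0
    per_view_rotation_spread_deg: float = 0.0
    per_view_translation_spread_mm: float = 0.0


def _radial_undistort(xg: np.ndarray, k1: float, k2: float, n_iter: int = 25) -> np.ndarray:
    """Damped-Newton inversion of the radial-only model (initialization use)."""
    x = xg.copy()
    for _ in range(n_iter):
        r2 = np.sum(x * x, axis=-1, keepdims=True)
        f = x * (1.0 + r2 * (k1 + r2 * k2)) - xg
        d = 1.0 + r2 * (3.0 * k1 + 5.0 * k2 * r2)
        d = np.where(np.abs(d) < 0.05, np.sign(d) * 0.05 + (d == 0) * 0.05, d)
        x = x - f / d
    return x


def _straightness_distortion(
    board: BoardModel, observations: list[BoardObservation], f0: float, cx0: float, cy0: float
) -> tuple[float, float]:
    """Pose-free radial-distortion seed from the straightness of board lines.

    Rows and columns of the checkerboard are straight in space, hence
    straight under an ideal pinhole; radial coefficients (in the trial
    normalization f0) are fit so the undistorted corners are collinear
    (the classical plumb-line constraint).  Robust to arbitrary board
    poses, so it survives view sets that defeat the conic closed form.
    """
    lines = []
    for obs in observations:
        groups: dict[tuple[str, int], list[np.ndarray]] = {}
        for cid, pix in zip(obs.corner_ids, obs.pixels):
            groups.setdefault(("r", int(cid) // board.n_cols), []).append(pix)
            groups.setdefault(("c", int(cid) % board.n_cols), []).append(pix)
        for pts in groups.values():
            if len(pts) < 4:
                continue
            arr = np.asarray(pts)
            # a heavily foreshortened (near edge-on) line spans only a few
            # pixels: its straightness is pure noise, so skip it
            span = np.linalg.norm(arr.max(axis=0) - arr.min(axis=0))
            if span < 150.0:
                continue
            lines.append((arr - [cx0, cy0]) / f0)
    if len(lines) < 6:
        return 0.0, 0.0
    if len(lines) > 400:
        idx = np.linspace(0, len(lines) - 1, 400).round().astype(int)
        lines = [lines[i] for i in sorted(set(idx))]

    pts = np.concatenate(lines)
    line_idx = np.concatenate([np.full(len(l), i) for i, l in enumerate(lines)])
    counts = np.bincount(line_idx).astype(float)

    def residuals(params):
        k1 = params[0]
        k2 = params[1] if len(params) > 1 else 0.0
        u = _radial_undistort(pts, k1, k2)
        cx = np.bincount(line_idx, u[:, 0]) / counts
        cy = np.bincount(line_idx, u[:, 1]) / counts
        dx = u[:, 0] - cx[line_idx]
        dy = u[:, 1] - cy[line_idx]
        sxx = np.bincount(line_idx, dx * dx)
        syy = np.bincount(line_idx, dy * dy)
        sxy = np.bincount(line_idx, dx * dy)
        # analytic principal direction of each line's 2x2 scatter
        phi = 0.5 * np.arctan2(2.0 * sxy, sxx - syy)
        d = dy * np.cos(phi)[line_idx] - dx * np.sin(phi)[line_idx]
        # normalize by the line's extent: the straightness objective must
        # be scale-invariant, else shrinking the image is a free lunch
        half = 0.5 * (sxx + syy)
        major = half + np.sqrt((0.5 * (sxx - syy)) ** 2 + sxy**2)
        extent = np.sqrt(np.maximum(major / counts, 1e-12))
        return d / extent[line_idx]

    # the straightness objective is multi-modal for one-sided line
    # coverage: start from several barrel/pincushion seeds, fit the
    # dominant k1 alone first (graduated model), then release k2 within a
    # physically sane box (runaway k2 can straighten noisy rim lines by
    # crushing them); among near-equal optima prefer the mildest k2
    k1_box, k2_box = 12.0, 25.0
    solutions = []
    for k1_start in (0.0, -1.0, -3.0, 1.0):
        s1 = least_squares(
            residuals, [k1_start], method="trf",
            bounds=([-k1_box], [k1_box]), max_nfev=200,
        )
        sol = least_squares(
            residuals, [float(s1.x[0]), 0.0], method="trf",
            bounds=([-k1_box, -k2_box], [k1_box, k2_box]), max_nfev=400,
        )
        solutions.append(sol)
    best_cost = min(s.cost for s in solutions)
    best = min(
        (s for s in solutions if s.cost <= 1.2 * best_cost),
        key=lambda s: abs(s.x[1]),
    )
    return float(best.x[0]), float(best.x[1])


def calibrate_intrinsics(
    board: BoardModel,
    observations: list[BoardObservation],
    image_size: tuple[int, int] = (2704, 1520),
    fix_k3: bool | None = None,
) -> IntrinsicCalibrationResult:
    """Calibrate one camera from >= 3 checkerboard views.

    Initialization is staged for robustness under strong distortion: a
    pose-free plumb-line fit straightens the board's rows and columns to
    seed the radial coefficients, the closed-form intrinsics (image of
    the absolute conic) are then computed from homographies on the
    straightened corners, and a damped least-squares refinement finally
    optimizes intrinsics + distortion + per-view poses against total
    squared reprojection error (several focal initializations are
    screened, since planar calibration has a spurious minimum trading
    focal length against depth).  ``k3`` is only estimated with >= 10
    views (an ill-conditioning guard) unless ``fix_k3`` overrides this.

    Returns intrinsics, distortion, per-view board->camera poses and the
    final reprojection RMSE in pixels (per pixel coordinate).
    """
    if len(observations) < 3:
        raise ValueError(f"intrinsic calibration needs >= 3 views, got {len(observations)}")
    camera_ids = {o.camera_id for o in observations}
    if len(camera_ids) > 1:
        raise ValueError(f"observations mix cameras: {sorted(camera_ids)}")
    board_pts = board.corner_points()

    homographies = []
    for obs in observations:
        if len(obs.corner_ids) < 4:
            raise DegenerateConfigurationError(
                f"view {obs.view_id!r} has fewer than 4 corners"
            )
        homographies.append(
            estimate_homography(board_pts[obs.corner_ids, :2], obs.pixels)
        )

    width, height = image_size
    cx0, cy0 = width / 2.0, height / 2.0
    f0 = float(width)

    # pose-free radial seed, then straightened pixels for the closed form
    k1p, k2p = _straightness_distortion(board, observations, f0, cx0, cy0)
    undistorted = []
    homographies_u = []
    for obs in observations:
        u = _radial_undistort((obs.pixels - [cx0, cy0]) / f0, k1p, k2p) * f0 + [cx0, cy0]
        undistorted.append(u)
        homographies_u.append(estimate_homography(board_pts[obs.corner_ids, :2], u))

    intr0 = _intrinsics_from_homographies(homographies_u, image_size)
    if intr0 is None:
        intr0 = _intrinsics_from_homographies(homographies, image_size)

    # view-diversity (degeneracy) check: board normals in the camera frame
    # must not all be parallel, else the conic constraints are rank-deficient
    probe = intr0 or Intrinsics(
        0.8 * width, 0.8 * width, width / 2.0, height / 2.0,
        image_width=width, image_height=height,
    )
    normals = np.asarray(
        [_pose_from_homography(h, probe.matrix)[0][:, 2] for h in homographies_u]
    )
    max_angle = np.degrees(
        np.arccos(np.clip(np.abs(normals @ normals.T), -1.0, 1.0)).max()
    )
    if max_angle < 3.0:
        raise DegenerateConfigurationError(
            f"board orientations are near-parallel (max {max_angle:.2f} deg apart); "
            "intrinsics are not identifiable from these views"
        )

    if fix_k3 is None:
        fix_k3 = len(observations) < 10

    n_views = len(observations)
    # parameter vector: fx fy cx cy skew | k1 k2 [k3] p1 p2 | (rvec tvec) per view
    dist_slice = slice(5, 9 if fix_k3 else 10)

    def unpack(params):
        intr_params = params[:5]
        d = params[dist_slice]
        dist_params = np.array([d[0], d[1], 0.0, d[2], d[3]]) if fix_k3 else d
        pose_params = params[dist_slice.stop :].reshape(n_views, 6)
        return intr_params, dist_params, pose_params

    # residuals vectorized over all views (corner counts may differ)
    all_pts = np.concatenate([board_pts[o.corner_ids] for o in observations])
    all_pix = np.concatenate([o.pixels for o in observations])
    view_idx = np.concatenate(
        [np.full(len(o.corner_ids), i) for i, o in enumerate(observations)]
    )

    def residuals(params):
        intr_params, dist_params, pose_params = unpack(params)
        r = Rotation.from_rotvec(pose_params[:, :3]).as_matrix()
        cam = (
            np.einsum("nij,nj->ni", r[view_idx], all_pts) + pose_params[view_idx, 3:]
        )
        pred = _distorted_pixels(cam, intr_params, dist_params)
        return (pred - all_pix).ravel()

    # planar calibration has a spurious minimum trading focal length
    # against depth, and strong distortion corrupts the closed-form
    # estimate; refine from several focal initializations, screen
    # cheaply, then polish the best
    def _fit_distortion_linear(intr: Intrinsics, poses) -> np.ndarray:
        # distortion is linear in its coefficients once K and the poses are
        # fixed: least-squares fit on normalized coordinates
        rows, rhs = [], []
        for obs, (r, t) in zip(observations, poses):
            cam_pts = board_pts[obs.corner_ids] @ r.T + t
            good = cam_pts[:, 2] > 1e-6
            xn = cam_pts[good, :2] / cam_pts[good, 2:3]
            yn = (obs.pixels[good, 1] - intr.cy) / intr.fy
            xo = (obs.pixels[good, 0] - intr.cx - intr.skew * yn) / intr.fx
            x, y = xn[:, 0], xn[:, 1]
            r2 = x * x + y * y
            row_x = [x * r2, x * r2**2] + ([] if fix_k3 else [x * r2**3]) + [
                2 * x * y, r2 + 2 * x * x,
            ]
            row_y = [y * r2, y * r2**2] + ([] if fix_k3 else [y * r2**3]) + [
                r2 + 2 * y * y, 2 * x * y,
            ]
            rows.append(np.column_stack(row_x))
            rows.append(np.column_stack(row_y))
            rhs.append(xo - x)
            rhs.append(yn - y)
        dist0, *_ = np.linalg.lstsq(np.vstack(rows), np.concatenate(rhs), rcond=None)
        return dist0

    def start_vector(intr: Intrinsics) -> np.ndarray:
        k = intr.matrix
        intr_arr = np.array([intr.fx, intr.fy, intr.cx, intr.cy, intr.skew])
        # poses from homographies on the straightened pixels; radial seed
        # rescaled from the plumb-line normalization into this candidate's
        scale = intr.fx / f0
        seed = np.array([k1p * scale**2, k2p * scale**4, 0.0, 0.0, 0.0])
        poses = []
        for obs, h in zip(observations, homographies_u):
            r, t = _pose_from_homography(h, k)

            def pose_res(p, pts_v=board_pts[obs.corner_ids], pix=obs.pixels):
                return (_project_board(pts_v, p[:3], p[3:], intr_arr, seed) - pix).ravel()

            s = least_squares(
                pose_res,
                np.concatenate([Rotation.from_matrix(r).as_rotvec(), t]),
                method="lm",
                max_nfev=200,
            )
            poses.append((Rotation.from_rotvec(s.x[:3]).as_matrix(), s.x[3:]))
        dist0 = _fit_distortion_linear(intr, poses)
        x0 = [intr.fx, intr.fy, intr.cx, intr.cy, intr.skew] + list(dist0)
        for r, t in poses:
            x0 += list(Rotation.from_matrix(r).as_rotvec()) + list(t)
        return np.asarray(x0)

    # with a successful straightened closed form the init is reliable and
    # one spare focal start suffices; otherwise spread over typical FOVs
    if intr0 is not None:
        fallback_ratios = (0.75,)
        candidates: list[Intrinsics] = [intr0]
    else:
        fallback_ratios = (0.3, 0.5, 0.75, 1.1)
        candidates = []
    for ratio in fallback_ratios:
        f = ratio * width
        if intr0 is not None and abs(f - intr0.fx) < 0.15 * width:
            continue
        candidates.append(
            Intrinsics(f, f, cx0, cy0, image_width=width, image_height=height)
        )

    # block-sparse jacobian: every residual sees the 9-10 global
    # parameters plus its own view's 6 pose parameters
    from scipy.sparse import lil_matrix

    n_params = dist_slice.stop + 6 * n_views
    sparsity = lil_matrix((2 * len(all_pts), n_params), dtype=int)
    sparsity[:, : dist_slice.stop] = 1
    for i in range(n_views):
        rows = np.flatnonzero(view_idx == i)
        rows = np.concatenate([2 * rows, 2 * rows + 1])
        sparsity[np.ix_(rows, np.arange(dist_slice.stop + 6 * i, dist_slice.stop + 6 * (i + 1)))] = 1

    ls_opts = dict(
        method="trf", x_scale="jac", tr_solver="lsmr", jac_sparsity=sparsity
    )
    screened = []
    for cand in candidates:
        x0 = start_vector(cand)
        s = least_squares(
            residuals, x0, ftol=1e-10, xtol=1e-10, gtol=1e-10, max_nfev=100, **ls_opts
        )
        screened.append(s)
    screened.sort(key=lambda s: s.cost)

    # polish the two best screened starts; basins can swap order early on
    polished = []
    for s in screened[:2]:
        polished.append(
            least_squares(
                residuals,
                s.x,
                ftol=_REFINE_TOL,
                xtol=_REFINE_TOL,
                gtol=_REFINE_TOL,
                max_nfev=_REFINE_MAX_ITER,
                **ls_opts,
            )
        )
    sol = min(polished, key=lambda s: s.cost)
    intr_params, dist_params, pose_params = unpack(sol.x)
    intrinsics = Intrinsics(
        *(float(p) for p in intr_params), image_width=width, image_height=height
    )
    distortion = Distortion(*(float(d) for d in dist_params))
    view_poses = {}
    for obs, pp in zip(observations, pose_params):
        view_poses[obs.view_id] = RigidTransform(
            Rotation.from_rotvec(pp[:3]).as_matrix(),
            pp[3:],
            source_frame="board",
            target_frame=f"camera:{obs.camera_id}",
        )
    return IntrinsicCalibrationResult(
        intrinsics=intrinsics,
        distortion=distortion,
        view_poses=view_poses,
        rmse_px=_reprojection_rmse(sol.fun),
        n_views=n_views,
    )


def estimate_board_pose(
    board: BoardModel,
    corner_ids: np.ndarray,
    pixels: np.ndarray,
    intrinsics: Intrinsics,
    distortion: Distortion,
) -> tuple[RigidTransform, float]:
    """Board->camera pose of one view from known intrinsics.

    Pixels are raw (distorted); they are undistorted internally, the pose
    is initialized by homography decomposition and refined by minimizing
    reprojection error through the full forward model.  Returns the pose
    and the per-coordinate reprojection RMSE (px).
    """
    corner_ids = np.asarray(corner_ids, dtype=int)
    pixels = np.asarray(pixels, dtype=float).reshape(-1, 2)
    if len(corner_ids) < 4:
        raise DegenerateConfigurationError(f"board pose needs >= 4 corners, got {len(corner_ids)}")
    board_pts = board.corner_points()[corner_ids]
    ideal = undistort_pixel(pixels, intrinsics, distortion)
    h = estimate_homography(board_pts[:, :2], ideal)
    r0, t0 = _pose_from_homography(h, intrinsics.matrix)

    intr_params = np.array(
        [intrinsics.fx, intrinsics.fy, intrinsics.cx, intrinsics.cy, intrinsics.skew]
    )
    dist_params = distortion.as_array()

    def residuals(params):
        pred = _project_board(board_pts, params[:3], params[3:], intr_params, dist_params)
        return (pred - pixels).ravel()

    x0 = np.concatenate([Rotation.from_matrix(r0).as_rotvec(), t0])
    sol = least_squares(
        residuals, x0, method="lm", ftol=_REFINE_TOL, xtol=_REFINE_TOL,
        max_nfev=_REFINE_MAX_ITER * 6,
    )
    pose = RigidTransform(
        Rotation.from_rotvec(sol.x[:3]).as_matrix(),
        sol.x[3:],
        source_frame="board",
        target_frame="camera",
    )
    return pose, _reprojection_rmse(sol.fun)


def _mean_rotation(rotations: list[np.ndarray]) -> np.ndarray:
    return Rotation.from_matrix(np.array(rotations)).mean().as_matrix()


def calibrate_stereo(
    board: BoardModel,
    observations_a: list[BoardObservation],
    observations_b: list[BoardObservation],
    intrinsics_a: Intrinsics,
    distortion_a: Distortion,
    intrinsics_b: Intrinsics,
    distortion_b: Distortion,
    max_rotation_spread_deg: float = 5.0,
    max_translation_spread_mm: float = 150.0,
) -> StereoCalibrationResult:
    """Relative pose camera_a -> camera_b from simultaneous board views.

    Views are matched by ``view_id``.  Requires >= 3 matched views; below
    the protocol minimum of 15 a warning is logged (the protocol states a
    recommended minimum, not an algorithmic one).  Per-view relative poses
    whose spread exceeds the configured limits raise an error suggesting
    mis-synchronized views.
    """
    by_view_a = {o.view_id: o for o in observations_a}
    by_view_b = {o.view_id: o for o in observations_b}
    shared = sorted(set(by_view_a) & set(by_view_b))
    shared = [v for v in shared if len(by_view_a[v].corner_ids) >= 4 and len(by_view_b[v].corner_ids) >= 4]
    if len(shared) < 3:
        raise ValueError(f"stereo calibration needs >= 3 paired views, got {len(shared)}")
    if len(shared) < MIN_STEREO_PAIRS:
        logger.warning(
            "stereo calibration with %d paired views (protocol minimum is %d)",
            len(shared),
            MIN_STEREO_PAIRS,
        )
    cam_a = observations_a[0].camera_id
    cam_b = observations_b[0].camera_id

    rel_rotations, rel_translations = [], []
    poses_a = {}
    for view in shared:
        pose_a, _ = estimate_board_pose(
            board, by_view_a[view].corner_ids, by_view_a[view].pixels, intrinsics_a, distortion_a
        )
        pose_b, _ = estimate_board_pose(
            board, by_view_b[view].corner_ids, by_view_b[view].pixels, intrinsics_b, distortion_b
        )
        # camera_a -> camera_b = (board->b) o (board->a)^-1
        r_rel = pose_b.rotation @ pose_a.rotation.T
        t_rel = pose_b.translation - r_rel @ pose_a.translation
        rel_rotations.append(r_rel)
        rel_translations.append(t_rel)
        poses_a[view] = pose_a

    r_mean = _mean_rotation(rel_rotations)
    t_med = np.median(np.array(rel_translations), axis=0)
    rot_spread = max(rotation_angle_deg(r_mean.T @ r) for r in rel_rotations)
    trans_spread = float(np.max(np.linalg.norm(np.array(rel_translations) - t_med, axis=1)))
    if rot_spread > max_rotation_spread_deg or trans_spread > max_translation_spread_mm:
        raise ValueError(
            f"per-view relative poses are inconsistent (rotation spread "
            f"{rot_spread:.2f} deg, translation spread {trans_spread:.1f} mm); "
            "are the paired views mis-synchronized?"
        )

    board_pts = board.corner_points()
    intr_a = np.array([intrinsics_a.fx, intrinsics_a.fy, intrinsics_a.cx, intrinsics_a.cy, intrinsics_a.skew])
    intr_b = np.array([intrinsics_b.fx, intrinsics_b.fy, intrinsics_b.cx, intrinsics_b.cy, intrinsics_b.skew])
    dist_a = distortion_a.as_array()
    dist_b = distortion_b.as_array()
    n_views = len(shared)

    pts_a = np.concatenate([board_pts[by_view_a[v].corner_ids] for v in shared])
    pix_a = np.concatenate([by_view_a[v].pixels for v in shared])
    idx_a = np.concatenate(
        [np.full(len(by_view_a[v].corner_ids), i) for i, v in enumerate(shared)]
    )
    pts_b = np.concatenate([board_pts[by_view_b[v].corner_ids] for v in shared])
    pix_b = np.concatenate([by_view_b[v].pixels for v in shared])
    idx_b = np.concatenate(
        [np.full(len(by_view_b[v].corner_ids), i) for i, v in enumerate(shared)]
    )

    def residuals(params):
        r_rel = Rotation.from_rotvec(params[:3]).as_matrix()
        rel_tvec = params[3:6]
        pose_params = params[6:].reshape(n_views, 6)
        r_views = Rotation.from_rotvec(pose_params[:, :3]).as_matrix()
        t_views = pose_params[:, 3:]
        cam_a_pts = np.einsum("nij,nj->ni", r_views[idx_a], pts_a) + t_views[idx_a]
        pred_a = _distorted_pixels(cam_a_pts, intr_a, dist_a)
        # board -> b composed from board -> a and a -> b
        r_vb = np.einsum("ij,njk->nik", r_rel, r_views)
        t_vb = t_views @ r_rel.T + rel_tvec
        cam_b_pts = np.einsum("nij,nj->ni", r_vb[idx_b], pts_b) + t_vb[idx_b]
        pred_b = _distorted_pixels(cam_b_pts, intr_b, dist_b)
        return np.concatenate(
            [(pred_a - pix_a).ravel(), (pred_b - pix_b).ravel()]
        )

    x0 = list(Rotation.from_matrix(r_mean).as_rotvec()) + list(t_med)
    for view in shared:
        p = poses_a[view]
        x0 += list(Rotation.from_matrix(p.rotation).as_rotvec()) + list(p.translation)
    x0 = np.asarray(x0)

    # block-sparse jacobian: camera-a residuals see only their view's
    # board pose; camera-b residuals additionally see the relative pose
    from scipy.sparse import lil_matrix

    n_a = 2 * len(pts_a)
    sparsity = lil_matrix((n_a + 2 * len(pts_b), 6 + 6 * n_views), dtype=int)
    sparsity[n_a:, :6] = 1
    for i in range(n_views):
        cols = np.arange(6 + 6 * i, 6 + 6 * (i + 1))
        rows_a = np.flatnonzero(idx_a == i)
        rows_b = np.flatnonzero(idx_b == i)
        rows = np.concatenate(
            [2 * rows_a, 2 * rows_a + 1, n_a + 2 * rows_b, n_a + 2 * rows_b + 1]
        )
        sparsity[np.ix_(rows, cols)] = 1

    sol = least_squares(
        residuals,
        x0,
        method="trf",
        x_scale="jac",
        tr_solver="lsmr",
        jac_sparsity=sparsity,
        ftol=_REFINE_TOL,
        xtol=_REFINE_TOL,
        gtol=_REFINE_TOL,
        max_nfev=_REFINE_MAX_ITER,
    )
    transform = RigidTransform(
        Rotation.from_rotvec(sol.x[:3]).as_matrix(),
        sol.x[3:6],
        source_frame=f"camera:{cam_a}",
        target_frame=f"camera:{cam_b}",
    )
    return StereoCalibrationResult(
        transform=transform,
        rmse_px=_reprojection_rmse(sol.fun),
        n_views=n_views,
        per_view_rotation_spread_deg=rot_spread,
        per_view_translation_spread_mm=trans_spread,
    )


def build_camera_model(
    camera_id: str, result: IntrinsicCalibrationResult, pose: RigidTransform | None = None
) -> CameraModel:
    """Convenience: assemble a CameraModel from a calibration result."""
    return CameraModel(
        camera_id=camera_id,
        intrinsics=result.intrinsics,
        distortion=result.distortion,
        pose=pose if pose is not None else RigidTransform.identity(f"camera:{camera_id}"),
    )
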