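"""Pinhole camera model, lens distortion, and rigid-transform algebra.

Conventions used throughout the package:

* World units are millimetres; every coordinate frame is right-handed.
* Camera frame: optical axis along +z, x to the right, y down.
* Pixel origin at the top-left image corner, u right, v down, sub-pixel
  continuous values.
* A camera pose is stored as the world->camera transform; the inverse is
  always derived, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Intrinsics",
    "Distortion",
    "RigidTransform",
    "CameraModel",
    "PointBehindCameraError",
    "FrameMismatchError",
    "UndistortionError",
    "project",
    "distort_normalized",
    "undistort_pixel",
    "projection_matrix",
    "compose",
    "invert",
]

#: orthonormality tolerance for rotation matrices
ROTATION_ATOL = 1e-9


class PointBehindCameraError(ValueError):
    """A 3D point has non-positive depth in the camera frame."""


class FrameMismatchError(ValueError):
    """Two rigid transforms with incompatible coordinate-frame tags."""


class UndistortionError(RuntimeError):
    """Iterative distortion inversion failed to converge."""

    def __init__(self, residual: float, tol: float):
        self.residual = residual
        super().__init__(
            f"undistortion did not converge: residual {residual:.3e} "
            f"(tolerance {tol:.1e} normalized units)"
        )


@dataclass(frozen=True)
class Intrinsics:
    """Internal camera parameters (pixel units).

    ``fx``/``fy`` are focal lengths, ``cx``/``cy`` the principal point,
    ``skew`` the (usually zero) axis skew.  Defaults match a 2.7K sensor.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    skew: float = 0.0
    image_width: int = 2704
    image_height: int = 1520

    def __post_init__(self):
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError(f"focal lengths must be positive, got fx={self.fx}, fy={self.fy}")
        if not (self.image_width > 0 and self.image_height > 0):
            raise ValueError("image dimensions must be positive")

    @property
    def matrix(self) -> np.ndarray:
        """The 3x3 calibration matrix K."""
        return np.array(
            [
                [self.fx, self.skew, self.cx],
                [0.0, self.fy, self.cy],
                [0.0, 0.0, 1.0],
            ]
        )


@dataclass(frozen=True)
class Distortion:
    """Brown-Conrady lens distortion on normalized image coordinates.

    Radial coefficients ``k1, k2, k3`` and tangential ``p1, p2``; the
    all-zero vector is an ideal pinhole.
    """

    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0

    def __post_init__(self):
        coeffs = (self.k1, self.k2, self.k3, self.p1, self.p2)
        if not all(np.isfinite(coeffs)):
            raise ValueError(f"distortion coefficients must be finite, got {coeffs}")

    @property
    def is_zero(self) -> bool:
        return self.k1 == self.k2 == self.k3 == self.p1 == self.p2 == 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.p1, self.p2])


def _check_rotation(rotation: np.ndarray) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got shape {rotation.shape}")
    if not np.allclose(rotation.T @ rotation, np.eye(3), atol=ROTATION_ATOL):
        raise ValueError("rotation matrix is not orthonormal within 1e-9")
    if not np.isclose(np.linalg.det(rotation), 1.0, atol=ROTATION_ATOL):
        raise ValueError("rotation matrix determinant is not +1 (improper rotation)")
    return rotation


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x_target = R @ x_source + t`` between two
    named coordinate frames (the "transition matrix" of the pipeline).

    ``translation`` is in mm.  Orthonormality and det(+1) are enforced at
    construction to 1e-9.
    """

    rotation: np.ndarray
    translation: np.ndarray
    source_frame: str = "world"
    target_frame: str = "camera"

    def __post_init__(self):
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls, frame: str = "world") -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), source_frame=frame, target_frame=frame)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform one (3,) point or an (N, 3) array of points."""
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    @property
    def matrix(self) -> np.ndarray:
        """The 4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform mapping ``self.source_frame`` to ``other.target_frame``.

        ``self`` maps A->B, ``other`` maps B->C; result maps A->C.
        """
        if self.target_frame != other.source_frame:
            raise FrameMismatchError(
                f"cannot chain {self.source_frame}->{self.target_frame} with "
                f"{other.source_frame}->{other.target_frame}: "
                f"{self.target_frame!r} != {other.source_frame!r}"
            )
        rotation = other.rotation @ self.rotation
        # re-orthonormalize to keep long chains within tolerance
        u, _, vt = np.linalg.svd(rotation)
        rotation = u @ vt
        return RigidTransform(
            rotation,
            other.rotation @ self.translation + other.translation,
            source_frame=self.source_frame,
            target_frame=other.target_frame,
        )

    def invert(self) -> "RigidTransform":
        return RigidTransform(
            self.rotation.T,
            -self.rotation.T @ self.translation,
            source_frame=self.target_frame,
            target_frame=self.source_frame,
        )

    def with_frames(self, source_frame: str, target_frame: str) -> "RigidTransform":
        return replace(self, source_frame=source_frame, target_frame=target_frame)


def compose(t_ab: RigidTransform, t_bc: RigidTransform) -> RigidTransform:
    """Chain A->B with B->C into A->C (functional form)."""
    return t_ab.compose(t_bc)


def invert(t: RigidTransform) -> RigidTransform:
    return t.invert()


@dataclass(frozen=True)
class CameraModel:
    """A calibrated camera: intrinsics, distortion, and a world->camera pose."""

    camera_id: str
    intrinsics: Intrinsics
    distortion: Distortion = field(default_factory=Distortion)
    pose: RigidTransform = field(default_factory=RigidTransform.identity)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def distort_normalized(xy: np.ndarray, distortion: Distortion) -> np.ndarray:
    """Apply radial + tangential distortion to normalized coordinates.

    ``xy`` is (..., 2).  Returns distorted normalized coordinates of the
    same shape.
    """
    xy = np.asarray(xy, dtype=float)
    x, y = xy[..., 0], xy[..., 1]
    r2 = x * x + y * y
    k1, k2, k3, p1, p2 = distortion.k1, distortion.k2, distortion.k3, distortion.p1, distortion.p2
    radial = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
    xd = x * radial + 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
    yd = y * radial + p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
    return np.stack([xd, yd], axis=-1)


def _normalized_to_pixel(xy: np.ndarray, intr: Intrinsics) -> np.ndarray:
    u = intr.fx * xy[..., 0] + intr.skew * xy[..., 1] + intr.cx
    v = intr.fy * xy[..., 1] + intr.cy
    return np.stack([u, v], axis=-1)


def _pixel_to_normalized(uv: np.ndarray, intr: Intrinsics) -> np.ndarray:
    uv = np.asarray(uv, dtype=float)
    y = (uv[..., 1] - intr.cy) / intr.fy
    x = (uv[..., 0] - intr.cx - intr.skew * y) / intr.fx
    return np.stack([x, y], axis=-1)


def project(point_world: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Project world points (mm) to pixel coordinates.

    Accepts a single (3,) point or an (N, 3) array.  Points must have
    positive depth in the camera frame; a non-positive depth raises
    :class:`PointBehindCameraError`.
    """
    pts = np.asarray(point_world, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    cam_pts = camera.pose.apply(pts)
    z = cam_pts[:, 2]
    if np.any(z <= 0):
        n_bad = int(np.sum(z <= 0))
        raise PointBehindCameraError(
            f"{n_bad} point(s) have non-positive depth in camera "
            f"{camera.camera_id!r} (min z = {z.min():.3f} mm)"
        )
    normalized = cam_pts[:, :2] / z[:, None]
    distorted = distort_normalized(normalized, camera.distortion)
    pix = _normalized_to_pixel(distorted, camera.intrinsics)
    return pix[0] if single else pix


def project_valid(points_world: np.ndarray, camera: CameraModel) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized projection that flags instead of raising.

    Returns ``(pixels, visible)`` where ``visible`` is False for points
    behind the camera or projecting outside the image bounds.  Pixels of
    invisible points are NaN.
    """
    pts = np.atleast_2d(np.asarray(points_world, dtype=float))
    cam_pts = camera.pose.apply(pts)
    z = cam_pts[:, 2]
    in_front = z > 1e-9
    pix = np.full((len(pts), 2), np.nan)
    if np.any(in_front):
        normalized = cam_pts[in_front, :2] / z[in_front, None]
        distorted = distort_normalized(normalized, camera.distortion)
        pix[in_front] = _normalized_to_pixel(distorted, camera.intrinsics)
    intr = camera.intrinsics
    with np.errstate(invalid="ignore"):
        in_image = (
            (pix[:, 0] >= 0.0)
            & (pix[:, 0] <= intr.image_width - 1)
            & (pix[:, 1] >= 0.0)
            & (pix[:, 1] <= intr.image_height - 1)
        )
    visible = in_front & in_image
    pix[~visible] = np.nan
    return pix, visible


def undistort_pixel(
    pixel: np.ndarray,
    intrinsics: Intrinsics,
    distortion: Distortion,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> np.ndarray:
    """Invert the distortion map: distorted pixel -> ideal pinhole pixel.

    Newton iteration on normalized coordinates (the plain fixed-point
    update is not contractive near the image corners for strong barrel
    distortion), to ``tol`` normalized units (default 1e-10) within
    ``max_iter`` iterations.  Raises :class:`UndistortionError` on
    non-convergence, reporting the last residual.
    """
    pixel = np.asarray(pixel, dtype=float)
    if not np.all(np.isfinite(pixel)):
        raise ValueError("pixel coordinates must be finite")
    if distortion.is_zero:
        return pixel.copy()
    single = pixel.ndim == 1
    uv = np.atleast_2d(pixel)
    xd = _pixel_to_normalized(uv, intrinsics)
    x = xd.copy()
    k1, k2, k3 = distortion.k1, distortion.k2, distortion.k3
    p1, p2 = distortion.p1, distortion.p2
    residual = np.inf
    for _ in range(max_iter):
        f = distort_normalized(x, distortion) - xd
        residual = float(np.max(np.abs(f))) if x.size else 0.0
        if residual < tol:
            break
        xx, yy = x[..., 0], x[..., 1]
        r2 = xx * xx + yy * yy
        radial = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
        dr = k1 + r2 * (2.0 * k2 + 3.0 * k3 * r2)  # d(radial)/d(r2)
        j11 = radial + 2.0 * xx * xx * dr + 2.0 * p1 * yy + 6.0 * p2 * xx
        j22 = radial + 2.0 * yy * yy * dr + 6.0 * p1 * yy + 2.0 * p2 * xx
        j12 = 2.0 * xx * yy * dr + 2.0 * p1 * xx + 2.0 * p2 * yy
        det = j11 * j22 - j12 * j12
        if np.any(np.abs(det) < 1e-15):
            raise UndistortionError(residual, tol)
        dx = (j22 * f[..., 0] - j12 * f[..., 1]) / det
        dy = (j11 * f[..., 1] - j12 * f[..., 0]) / det
        x = x - np.stack([dx, dy], axis=-1)
    else:
        raise UndistortionError(residual, tol)
    out = _normalized_to_pixel(x, intrinsics)
    return out[0] if single else out


def projection_matrix(camera: CameraModel) -> np.ndarray:
    """The 3x4 DLT projection matrix ``K [R | t]``.

    Operates on undistorted observations only: the distortion component of
    the camera model is deliberately not representable here.
    """
    rt = np.hstack([camera.pose.rotation, camera.pose.translation[:, None]])
    return camera.intrinsics.matrix @ rt


def rotation_angle_deg(rotation: np.ndarray) -> float:
    """Rotation angle of a 3x3 rotation matrix, in degrees."""
    c = (np.trace(rotation) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
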