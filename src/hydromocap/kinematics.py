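"""Equine joint angles, range of motion, and swim-cycle detection.

Eight joints are tracked, four per limb.  Each joint angle is the interior
angle at a vertex marker between the proximal and distal limb segments
(e.g. the shoulder angle is formed between the scapula and the humerus,
with the vertex at the shoulder marker).  Flexion decreases the angle,
extension increases it; the fetlocks hyperextend past the straight-joint
value of 180 deg, so a signed convention is needed: the cross product of
the two limb vectors is tested against a lateral (medio-lateral) axis —
swimming motion is mainly confined to the sagittal plane, so the
pool-frame x axis serves as the default lateral axis.  A negative
projection marks hyperextension and the reported angle becomes
360 - theta, allowing values above 180 deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .geometry import RigidTransform
from .reconstruction import Trajectory3D

__all__ = [
    "JointDefinition",
    "AngleSeries",
    "RomSummary",
    "JOINT_DEFINITIONS",
    "FRONT_LIMB_JOINTS",
    "HIND_LIMB_JOINTS",
    "joint_angle",
    "joint_angle_series",
    "summarize_rom",
    "detect_cycles",
    "lowpass_angle_series",
]

#: default lateral axis: the pool-frame x axis (medio-lateral direction)
DEFAULT_LATERAL_AXIS = np.array([1.0, 0.0, 0.0])


@dataclass(frozen=True)
class JointDefinition:
    """Marker triple defining one joint angle.

    ``proximal`` - ``vertex`` - ``distal`` anatomical marker labels; the
    angle vertex sits at the joint.  ``lateral_axis`` disambiguates
    hyperextension; flip its sign to flip the convention for a joint.
    """

    name: str
    proximal: str
    vertex: str
    distal: str
    lateral_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self):
        if len({self.proximal, self.vertex, self.distal}) != 3:
            raise ValueError(f"joint {self.name!r} needs three distinct marker labels")


FRONT_LIMB_JOINTS: tuple[JointDefinition, ...] = (
    JointDefinition("shoulder", "scapular_spine", "shoulder", "elbow"),
    JointDefinition("elbow", "shoulder", "elbow", "carpus"),
    JointDefinition("carpus", "elbow", "carpus", "front_fetlock"),
    JointDefinition("front_fetlock", "carpus", "front_fetlock", "front_hoof"),
)

HIND_LIMB_JOINTS: tuple[JointDefinition, ...] = (
    JointDefinition("hip", "tuber_coxae", "hip", "stifle"),
    JointDefinition("stifle", "hip", "stifle", "tarsus"),
    JointDefinition("tarsus", "stifle", "tarsus", "hind_fetlock"),
    JointDefinition("hind_fetlock", "tarsus", "hind_fetlock", "hind_hoof"),
)

#: the eight canonical joints: shoulder, elbow, carpus, front fetlock,
#: hip, stifle, tarsus, hind fetlock
JOINT_DEFINITIONS: tuple[JointDefinition, ...] = FRONT_LIMB_JOINTS + HIND_LIMB_JOINTS


@dataclass
class AngleSeries:
    """Frame-indexed joint angle in degrees, open interval (0, 360)."""

    joint: str
    frames: np.ndarray
    angles_deg: np.ndarray
    frame_rate: float = 120.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int).reshape(-1)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float).reshape(-1)
        if len(self.frames) != len(self.angles_deg):
            raise ValueError("frames and angles length mismatch")
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frame indices must be strictly increasing")


@dataclass(frozen=True)
class RomSummary:
    """Maximal flexion (series minimum), maximal extension (maximum), ROM."""

    maximal_flexion: float
    maximal_extension: float
    rom: float = field(default=0.0)

    def __post_init__(self):
        object.__setattr__(self, "rom", self.maximal_extension - self.maximal_flexion)
        if self.rom < 0:
            raise ValueError("maximal_extension must be >= maximal_flexion")


def joint_angle(
    p_prox: np.ndarray,
    p_vertex: np.ndarray,
    p_dist: np.ndarray,
    lateral_axis: np.ndarray = DEFAULT_LATERAL_AXIS,
) -> float:
    """Joint angle in degrees at ``p_vertex``, hyperextension-aware.

    The unsigned angle theta between (p_prox - p_vertex) and
    (p_dist - p_vertex) lies in [0, 180]; if the cross product of the two
    vectors points against the lateral axis the joint is hyperextended and
    360 - theta is returned.
    """
    v1 = np.asarray(p_prox, dtype=float) - np.asarray(p_vertex, dtype=float)
    v2 = np.asarray(p_dist, dtype=float) - np.asarray(p_vertex, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("zero-length limb vector at the joint vertex")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    theta = float(np.degrees(np.arccos(cosang)))
    if np.dot(np.cross(v1, v2), np.asarray(lateral_axis, dtype=float)) < 0:
        return 360.0 - theta
    return theta


def _joint_angles_vec(v1: np.ndarray, v2: np.ndarray, lateral_axis: np.ndarray) -> np.ndarray:
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    if np.any(n1 < 1e-12) or np.any(n2 < 1e-12):
        raise ValueError("zero-length limb vector at the joint vertex")
    cosang = np.clip(np.sum(v1 * v2, axis=1) / (n1 * n2), -1.0, 1.0)
    theta = np.degrees(np.arccos(cosang))
    hyper = np.cross(v1, v2) @ lateral_axis < 0
    theta[hyper] = 360.0 - theta[hyper]
    return theta


def joint_angle_series(
    trajectories: dict[str, Trajectory3D],
    definitions: tuple[JointDefinition, ...] = JOINT_DEFINITIONS,
    frame_rate: float = 120.0,
) -> dict[str, AngleSeries]:
    """Per-frame joint angles for every joint whose markers are present.

    All three marker trajectories of a joint must exist and share a
    coordinate frame; the angle is computed at frames where all three are
    visible.  A missing marker label raises an error naming the joint.
    """
    out: dict[str, AngleSeries] = {}
    for jd in definitions:
        missing = [lbl for lbl in (jd.proximal, jd.vertex, jd.distal) if lbl not in trajectories]
        if missing:
            raise KeyError(f"joint {jd.name!r}: missing marker trajectories {missing}")
        tp, tv, td = trajectories[jd.proximal], trajectories[jd.vertex], trajectories[jd.distal]
        frames_set = {tp.coordinate_frame, tv.coordinate_frame, td.coordinate_frame}
        if len(frames_set) != 1:
            raise ValueError(
                f"joint {jd.name!r}: marker trajectories in different coordinate "
                f"frames {sorted(frames_set)}"
            )
        common = np.intersect1d(np.intersect1d(tp.frames, tv.frames), td.frames)
        idx_p = np.searchsorted(tp.frames, common)
        idx_v = np.searchsorted(tv.frames, common)
        idx_d = np.searchsorted(td.frames, common)
        lateral = np.asarray(jd.lateral_axis, dtype=float)
        angles = _joint_angles_vec(
            tp.points[idx_p] - tv.points[idx_v],
            td.points[idx_d] - tv.points[idx_v],
            lateral,
        )
        out[jd.name] = AngleSeries(jd.name, common, angles, frame_rate)
    return out


def summarize_rom(series: AngleSeries) -> RomSummary:
    """Maximal flexion (minimum angle), maximal extension (maximum), ROM.

    Smaller angle means more flexed; ROM is extension minus flexion.
    """
    if len(series.angles_deg) == 0:
        raise ValueError(f"empty angle series for joint {series.joint!r}")
    flexion = float(series.angles_deg.min())
    extension = float(series.angles_deg.max())
    return RomSummary(maximal_flexion=flexion, maximal_extension=extension)


def detect_cycles(
    series: AngleSeries,
    min_period_s: float = 1.0,
    frame_rate: float | None = None,
) -> tuple[list[int], list[float]]:
    """Swim-cycle boundaries and durations from extension peaks.

    Boundaries are successive maxima of the angle series separated by at
    least ``min_period_s``; durations (s) are the spacings divided by the
    frame rate.  Fewer than two peaks yields an empty result.
    """
    fs = frame_rate if frame_rate is not None else series.frame_rate
    angles = series.angles_deg
    if len(angles) < 3:
        return [], []
    spread = float(angles.max() - angles.min())
    if spread < 1e-9:
        return [], []
    distance = max(1, int(round(min_period_s * fs)))
    peaks, _ = find_peaks(angles, distance=distance, prominence=0.1 * spread)
    boundaries = [int(series.frames[p]) for p in peaks]
    if len(boundaries) < 2:
        return [], []
    durations = [float(b2 - b1) / fs for b1, b2 in zip(boundaries, boundaries[1:])]
    return boundaries, durations


def lowpass_angle_series(series: AngleSeries, cutoff_hz: float = 6.0, order: int = 4) -> AngleSeries:
    """Optional zero-phase Butterworth low-pass of an angle series.

    Off by default in the pipeline; useful to suppress tracking noise
    before extrema-based summaries.  Requires a contiguous series.
    """
    if len(series.frames) > 1 and np.any(np.diff(series.frames) != 1):
        raise ValueError("low-pass filtering requires a gap-free series")
    if len(series.angles_deg) < 3 * (order + 1):
        return series
    b, a = butter(order, cutoff_hz / (series.frame_rate / 2.0))
    smoothed = filtfilt(b, a, series.angles_deg)
    return AngleSeries(series.joint, series.frames.copy(), smoothed, series.frame_rate)


def rigid_transform_series(
    trajectories: dict[str, Trajectory3D], transform: RigidTransform
) -> dict[str, Trajectory3D]:
    """Apply one rigid transform to every trajectory (convenience)."""
    return {lbl: t.transformed(transform) for lbl, t in trajectories.items()}
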