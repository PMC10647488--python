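"""File formats: CSV dialects, rig configuration (YAML/JSON), TRC export.

All numeric round trips are lossless at full float precision (values are
written with ``repr`` precision).  Unknown columns are ignored with a
warning; missing required columns raise an error naming the column.

CSV dialects
------------
tracks        frame, camera_id, label, u_px, v_px, visible
trajectories  frame, label, x_mm, y_mm, z_mm, coordinate_frame
luminance     camera_id, frame, luminance
board         view_id, camera_id, corner_id, u_px, v_px
angles        frame, joint, angle_deg
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import BoardObservation
from .geometry import CameraModel, Distortion, Intrinsics, RigidTransform
from .kinematics import AngleSeries, RomSummary
from .reconstruction import MarkerTrack2D, Trajectory3D
from .synchronization import LuminanceSeries, SyncResult

__all__ = [
    "read_tracks", "write_tracks",
    "read_trajectories", "write_trajectories",
    "read_luminance", "write_luminance",
    "read_board_observations", "write_board_observations",
    "read_rig_config", "write_rig_config",
    "read_angle_series", "write_angle_series",
    "write_rom_summaries", "read_rom_summaries",
    "read_sync", "write_sync",
    "write_trc",
    "MissingColumnError",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


class MissingColumnError(ValueError):
    def __init__(self, column: str, path):
        self.column = column
        super().__init__(f"required column {column!r} missing from {path}")


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    # round_trip parsing: the default fast parser is up to 2 ulp off,
    # breaking the lossless-round-trip contract
    df = pd.read_csv(path, float_precision="round_trip")
    for col in required:
        if col not in df.columns:
            raise MissingColumnError(col, path)
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("ignoring unknown columns %s in %s", extra, path)
    return df[required]


# -- tracks ------------------------------------------------------------------

def write_tracks(tracks: list[MarkerTrack2D], path) -> None:
    rows = []
    for t in tracks:
        rows.append(
            pd.DataFrame(
                {
                    "frame": t.frames,
                    "camera_id": t.camera_id,
                    "label": t.label,
                    "u_px": t.pixels[:, 0],
                    "v_px": t.pixels[:, 1],
                    "visible": 1,
                }
            )
        )
    df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["frame", "camera_id", "label", "u_px", "v_px", "visible"])
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_tracks(path) -> list[MarkerTrack2D]:
    df = _read_csv(path, ["frame", "camera_id", "label", "u_px", "v_px", "visible"])
    df = df[df["visible"].astype(int) == 1]
    dup = df.duplicated(subset=["camera_id", "label", "frame"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            f"duplicate (camera, label, frame) sample in {path}: "
            f"({first['camera_id']}, {first['label']}, {first['frame']})"
        )
    tracks = []
    for (cam, label), grp in df.groupby(["camera_id", "label"], sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            MarkerTrack2D(
                str(cam), str(label),
                grp["frame"].to_numpy(int),
                grp[["u_px", "v_px"]].to_numpy(float),
            )
        )
    return tracks


# -- trajectories ------------------------------------------------------------

def write_trajectories(trajectories: dict[str, Trajectory3D] | list[Trajectory3D], path) -> None:
    trajs = list(trajectories.values()) if isinstance(trajectories, dict) else trajectories
    rows = []
    for t in trajs:
        rows.append(
            pd.DataFrame(
                {
                    "frame": t.frames,
                    "label": t.label,
                    "x_mm": t.points[:, 0],
                    "y_mm": t.points[:, 1],
                    "z_mm": t.points[:, 2],
                    "coordinate_frame": t.coordinate_frame,
                }
            )
        )
    df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["frame", "label", "x_mm", "y_mm", "z_mm", "coordinate_frame"])
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectories(path) -> dict[str, Trajectory3D]:
    df = _read_csv(path, ["frame", "label", "x_mm", "y_mm", "z_mm", "coordinate_frame"])
    out: dict[str, Trajectory3D] = {}
    for label, grp in df.groupby("label", sort=True):
        grp = grp.sort_values("frame")
        frames = set(grp["coordinate_frame"].unique())
        if len(frames) > 1:
            raise ValueError(f"label {label!r} mixes coordinate frames {sorted(frames)}")
        out[str(label)] = Trajectory3D(
            str(label),
            grp["frame"].to_numpy(int),
            grp[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
            str(grp["coordinate_frame"].iloc[0]),
        )
    return out


# -- luminance ---------------------------------------------------------------

def write_luminance(series: list[LuminanceSeries], path) -> None:
    rows = [
        pd.DataFrame(
            {
                "camera_id": s.camera_id,
                "frame": np.arange(len(s.luminance)),
                "luminance": s.luminance,
            }
        )
        for s in series
    ]
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_luminance(path, frame_rate: float = 120.0) -> list[LuminanceSeries]:
    df = _read_csv(path, ["camera_id", "frame", "luminance"])
    out = []
    for cam, grp in df.groupby("camera_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(LuminanceSeries(str(cam), grp["luminance"].to_numpy(float), frame_rate))
    return out


# -- board observations ------------------------------------------------------

def write_board_observations(observations: list[BoardObservation], path) -> None:
    rows = [
        pd.DataFrame(
            {
                "view_id": o.view_id,
                "camera_id": o.camera_id,
                "corner_id": o.corner_ids,
                "u_px": o.pixels[:, 0],
                "v_px": o.pixels[:, 1],
            }
        )
        for o in observations
    ]
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_board_observations(path) -> list[BoardObservation]:
    df = _read_csv(path, ["view_id", "camera_id", "corner_id", "u_px", "v_px"])
    out = []
    for (view, cam), grp in df.groupby(["view_id", "camera_id"], sort=True):
        out.append(
            BoardObservation(
                str(view), str(cam),
                grp["corner_id"].to_numpy(int),
                grp[["u_px", "v_px"]].to_numpy(float),
            )
        )
    return out


# -- rig configuration -------------------------------------------------------

def _transform_to_dict(t: RigidTransform) -> dict:
    return {
        "rotation": t.rotation.tolist(),
        "translation": t.translation.tolist(),
        "source_frame": t.source_frame,
        "target_frame": t.target_frame,
    }


def _transform_from_dict(d: dict) -> RigidTransform:
    return RigidTransform(
        np.asarray(d["rotation"], dtype=float),
        np.asarray(d["translation"], dtype=float),
        source_frame=d.get("source_frame", "world"),
        target_frame=d.get("target_frame", "camera"),
    )


def write_rig_config(
    cameras: dict[str, CameraModel],
    path,
    stereo: dict[str, RigidTransform] | None = None,
    frame_rate: float = 120.0,
) -> None:
    """Rig configuration file (YAML, or JSON if the suffix is .json).

    ``stereo`` transforms are keyed "camA:camB" (camera A frame to camera
    B frame).  Camera order in the file defines the pairing order used by
    the pipeline.
    """
    doc = {"frame_rate": frame_rate, "cameras": {}, "stereo": {}}
    for cam_id, cam in cameras.items():
        intr = cam.intrinsics
        doc["cameras"][cam_id] = {
            "intrinsics": {
                "fx": intr.fx, "fy": intr.fy, "cx": intr.cx, "cy": intr.cy,
                "skew": intr.skew,
            },
            "image_size": [intr.image_width, intr.image_height],
            "distortion": {
                "k1": cam.distortion.k1, "k2": cam.distortion.k2,
                "k3": cam.distortion.k3, "p1": cam.distortion.p1,
                "p2": cam.distortion.p2,
            },
            "pose": _transform_to_dict(cam.pose),
        }
    for key, t in (stereo or {}).items():
        doc["stereo"][key] = _transform_to_dict(t)
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(doc, fh, indent=1)
        else:
            yaml.safe_dump(doc, fh, sort_keys=False)


def read_rig_config(path) -> tuple[dict[str, CameraModel], dict[str, RigidTransform], float]:
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    cameras: dict[str, CameraModel] = {}
    for cam_id, c in doc["cameras"].items():
        intr = c["intrinsics"]
        w, h = c.get("image_size", [2704, 1520])
        intrinsics = Intrinsics(
            intr["fx"], intr["fy"], intr["cx"], intr["cy"], intr.get("skew", 0.0),
            image_width=int(w), image_height=int(h),
        )
        d = c.get("distortion", {})
        distortion = Distortion(
            d.get("k1", 0.0), d.get("k2", 0.0), d.get("k3", 0.0),
            d.get("p1", 0.0), d.get("p2", 0.0),
        )
        pose = (
            _transform_from_dict(c["pose"])
            if "pose" in c
            else RigidTransform.identity(f"camera:{cam_id}")
        )
        cameras[cam_id] = CameraModel(cam_id, intrinsics, distortion, pose)
    stereo = {key: _transform_from_dict(t) for key, t in doc.get("stereo", {}).items()}
    return cameras, stereo, float(doc.get("frame_rate", 120.0))


# -- angles / ROM ------------------------------------------------------------

def write_angle_series(series: dict[str, AngleSeries], path) -> None:
    rows = [
        pd.DataFrame({"frame": s.frames, "joint": s.joint, "angle_deg": s.angles_deg})
        for s in series.values()
    ]
    df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["frame", "joint", "angle_deg"])
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_angle_series(path, frame_rate: float = 120.0) -> dict[str, AngleSeries]:
    df = _read_csv(path, ["frame", "joint", "angle_deg"])
    out = {}
    for joint, grp in df.groupby("joint", sort=True):
        grp = grp.sort_values("frame")
        out[str(joint)] = AngleSeries(
            str(joint), grp["frame"].to_numpy(int), grp["angle_deg"].to_numpy(float), frame_rate
        )
    return out


def write_rom_summaries(summaries: dict[str, RomSummary], path) -> None:
    doc = {
        joint: {
            "maximal_flexion_deg": round(s.maximal_flexion, 2),
            "maximal_extension_deg": round(s.maximal_extension, 2),
            "rom_deg": round(s.rom, 2),
        }
        for joint, s in summaries.items()
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_rom_summaries(path) -> dict[str, RomSummary]:
    with open(path) as fh:
        doc = json.load(fh)
    return {
        joint: RomSummary(d["maximal_flexion_deg"], d["maximal_extension_deg"])
        for joint, d in doc.items()
    }


# -- synchronization ---------------------------------------------------------

def write_sync(sync: SyncResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "reference_camera_id": sync.reference_camera_id,
                "offsets": sync.offsets,
                "event_frames": sync.event_frames,
            },
            fh,
            indent=1,
        )


def read_sync(path) -> SyncResult:
    with open(path) as fh:
        doc = json.load(fh)
    return SyncResult(
        reference_camera_id=doc["reference_camera_id"],
        offsets={k: int(v) for k, v in doc["offsets"].items()},
        event_frames={k: list(map(int, v)) for k, v in doc.get("event_frames", {}).items()},
    )


# -- TRC export --------------------------------------------------------------

def write_trc(
    trajectories: dict[str, Trajectory3D], path, frame_rate: float = 120.0
) -> None:
    """Export trajectories as a TRC motion-capture file (mm units).

    Only frames present in every trajectory are exported (TRC is a dense
    format).  Coordinates are written in mm at the given rate.
    """
    labels = sorted(trajectories)
    if not labels:
        raise ValueError("no trajectories to export")
    common = trajectories[labels[0]].frames
    for lbl in labels[1:]:
        common = np.intersect1d(common, trajectories[lbl].frames)
    path = Path(path)
    n = len(common)
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(
            f"{frame_rate:g}\t{frame_rate:g}\t{n}\t{len(labels)}\tmm\t"
            f"{frame_rate:g}\t1\t{n}\n"
        )
        fh.write("Frame#\tTime\t" + "\t\t\t".join(labels) + "\t\t\t\n")
        sub = ["\t"] + [f"X{i}\tY{i}\tZ{i}" for i in range(1, len(labels) + 1)]
        fh.write("\t".join(sub) + "\n\n")
        for row_idx, frame in enumerate(common, start=1):
            time = frame / frame_rate
            cells = [str(row_idx), f"{time:.6f}"]
            for lbl in labels:
                t = trajectories[lbl]
                p = t.points[np.searchsorted(t.frames, frame)]
                cells.extend(f"{c:.6f}" for c in p)
            fh.write("\t".join(cells) + "\n")
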