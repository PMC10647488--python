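"""Checkerboard-based error estimation for the reconstruction pipeline.

Five labelled reference points on the calibration checkerboard (TL, TR,
ML, BL, BR) are reconstructed while the board sweeps across the rig.
Eight segments (340-600 mm) and five angles (34-101 deg) computed from the
reconstruction are compared against the board's known geometry, giving a
per-frame absolute error whose box-plot summary characterises the
accuracy of the whole chain (calibration, triangulation, unification).

Note on the reference angles: the angle ground truths are pinned to the
geometry implied by the printed side lengths (law of cosines), which puts
45.00 deg at vertex TL (angle ML-TL-TR) and 33.69 deg at vertex TR
(angle TL-TR-ML).  See the README for the labelling discrepancy this
resolves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reconstruction import Trajectory3D

__all__ = [
    "CheckerboardModel",
    "reference_geometry",
    "segment_errors",
    "angle_errors",
    "error_report",
    "REFERENCE_LABELS",
    "SEGMENTS",
    "ANGLES",
    "SEGMENT_GROUPS",
]

REFERENCE_LABELS = ("TL", "TR", "ML", "BL", "BR")

#: the eight evaluated segments (label pairs)
SEGMENTS: tuple[tuple[str, str], ...] = (
    ("TL", "TR"),
    ("BL", "BR"),
    ("TL", "BL"),
    ("TR", "BR"),
    ("TL", "ML"),
    ("BL", "ML"),
    ("TR", "ML"),
    ("BR", "ML"),
)

#: symmetric segment pairs pooled per box in the summary figures
SEGMENT_GROUPS: dict[str, tuple[str, ...]] = {
    "horizontal": ("TL-TR", "BL-BR"),
    "vertical": ("TL-BL", "TR-BR"),
    "first_diagonal": ("TL-ML", "BL-ML"),
    "second_diagonal": ("TR-ML", "BR-ML"),
}

#: the five evaluated angles: (name, (proximal, vertex, distal))
ANGLES: tuple[tuple[str, tuple[str, str, str]], ...] = (
    ("TL-ML-TR", ("TL", "ML", "TR")),
    ("ML-TL-TR", ("ML", "TL", "TR")),
    ("TL-TR-ML", ("TL", "TR", "ML")),
    ("TR-TL-BL", ("TR", "TL", "BL")),
    ("TR-BR-BL", ("TR", "BR", "BL")),
)

@dataclass(frozen=True)
class CheckerboardModel:
    """The five reference points with their ground-truth segments and angles.

    ``points`` maps labels to planar board-frame coordinates in mm (z = 0);
    ``segment_truths`` / ``angle_truths`` carry the ground-truth lengths
    (mm) and angles (deg) derived from those coordinates.
    """

    points: dict[str, np.ndarray]
    segment_truths: dict[str, float]
    angle_truths: dict[str, float]

    def point_array(self, labels=REFERENCE_LABELS) -> np.ndarray:
        return np.array([self.points[lbl] for lbl in labels])


def _angle_planar(points: dict[str, np.ndarray], triple: tuple[str, str, str]) -> float:
    p, v, d = (points[t] for t in triple)
    v1, v2 = p - v, d - v
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def reference_geometry(
    width: float = 600.0,
    height: float = 480.0,
    first_diagonal: float = 339.4,
    second_diagonal: float = 432.7,
) -> CheckerboardModel:
    """The reference five-point geometry of the validation checkerboard.

    TL = (0, 0), TR = (width, 0), BL = (0, height), BR = (width, height);
    ML is solved from the two-circle intersection |TL-ML| = first_diagonal
    and |TR-ML| = second_diagonal (planar, in the board frame).  With the
    printed lengths this puts ML at (240, 240) mm to within 0.05 mm.
    """
    x = (first_diagonal**2 - second_diagonal**2 + width**2) / (2.0 * width)
    y2 = first_diagonal**2 - x**2
    if y2 <= 0:
        raise ValueError("diagonal lengths are inconsistent with the board width")
    y = float(np.sqrt(y2))
    points = {
        "TL": np.array([0.0, 0.0, 0.0]),
        "TR": np.array([width, 0.0, 0.0]),
        "BL": np.array([0.0, height, 0.0]),
        "BR": np.array([width, height, 0.0]),
        "ML": np.array([x, y, 0.0]),
    }
    segment_truths = {
        f"{a}-{b}": float(np.linalg.norm(points[a] - points[b])) for a, b in SEGMENTS
    }
    # angles are unsigned (< 180 deg) so the in-plane sign convention is moot
    angle_truths = {name: _angle_planar(points, triple) for name, triple in ANGLES}
    return CheckerboardModel(points, segment_truths, angle_truths)


def _aligned_points(
    trajectories: dict[str, Trajectory3D], labels: tuple[str, ...]
) -> tuple[np.ndarray, dict[str, np.ndarray], int]:
    """Frames at which all requested labels are visible, and their points."""
    missing = [lbl for lbl in labels if lbl not in trajectories]
    if missing:
        raise KeyError(f"missing reference-point trajectories: {missing}")
    frames = trajectories[labels[0]].frames
    for lbl in labels[1:]:
        frames = np.intersect1d(frames, trajectories[lbl].frames)
    n_total = max(len(trajectories[lbl].frames) for lbl in labels)
    pts = {}
    for lbl in labels:
        t = trajectories[lbl]
        pts[lbl] = t.points[np.searchsorted(t.frames, frames)]
    return frames, pts, n_total - len(frames)


def segment_errors(
    trajectories: dict[str, Trajectory3D],
    model: CheckerboardModel,
    signed: bool = False,
) -> pd.DataFrame:
    """Per-frame segment-length errors of the eight evaluated segments.

    Returns a tidy frame with columns ``frame, item, value, error`` where
    ``value`` is the reconstructed length (mm) and ``error`` the absolute
    (or signed, if requested) deviation from ground truth.  Frames missing
    any of the five labels are skipped; their count is logged in the
    DataFrame attrs.
    """
    frames, pts, n_skipped = _aligned_points(trajectories, REFERENCE_LABELS)
    rows = []
    for a, b in SEGMENTS:
        name = f"{a}-{b}"
        lengths = np.linalg.norm(pts[a] - pts[b], axis=1)
        err = lengths - model.segment_truths[name]
        if not signed:
            err = np.abs(err)
        rows.append(pd.DataFrame({"frame": frames, "item": name, "value": lengths, "error": err}))
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    out.attrs["n_skipped_frames"] = int(n_skipped)
    return out


def angle_errors(
    trajectories: dict[str, Trajectory3D],
    model: CheckerboardModel,
    signed: bool = False,
) -> pd.DataFrame:
    """Per-frame angle errors of the five evaluated angles (degrees).

    Angles are unsigned (all reference angles are below 180 deg), so no
    lateral-axis convention is needed; the reconstruction's rigid pose
    drops out.
    """
    frames, pts, n_skipped = _aligned_points(trajectories, REFERENCE_LABELS)
    rows = []
    for name, (p, v, d) in ANGLES:
        v1 = pts[p] - pts[v]
        v2 = pts[d] - pts[v]
        cosang = np.clip(
            np.sum(v1 * v2, axis=1)
            / (np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)),
            -1.0,
            1.0,
        )
        ang = np.degrees(np.arccos(cosang))
        err = ang - model.angle_truths[name]
        if not signed:
            err = np.abs(err)
        rows.append(pd.DataFrame({"frame": frames, "item": name, "value": ang, "error": err}))
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    out.attrs["n_skipped_frames"] = int(n_skipped)
    return out


def _five_number(values: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()) if len(inside) else float(med),
        "whisker_high": float(inside.max()) if len(inside) else float(med),
        "n_outliers": int(np.sum((values < lo_fence) | (values > hi_fence))),
        "n": int(len(values)),
    }


def error_report(
    segment_err: pd.DataFrame, angle_err: pd.DataFrame
) -> dict[str, dict[str, dict[str, float]]]:
    """Box-plot style summaries (1.5 IQR whisker convention) of the errors.

    Per-item summaries for all eight segments and five angles, plus pooled
    summaries of the symmetric segment pairs (horizontal, vertical, first
    and second diagonals) as shown in the validation figures.
    """
    report: dict[str, dict[str, dict[str, float]]] = {
        "segments": {}, "segments_pooled": {}, "angles": {},
    }
    for item, grp in segment_err.groupby("item"):
        report["segments"][item] = _five_number(grp["error"].to_numpy())
    for group_name, items in SEGMENT_GROUPS.items():
        pooled = segment_err[segment_err["item"].isin(items)]["error"].to_numpy()
        if len(pooled):
            report["segments_pooled"][group_name] = _five_number(pooled)
    for item, grp in angle_err.groupby("item"):
        report["angles"][item] = _five_number(grp["error"].to_numpy())
    return report
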