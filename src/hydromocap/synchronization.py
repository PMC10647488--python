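"""Event-based camera synchronization from lighting-extinction dips.

The six cameras free-run on a nominal shared 120 fps clock; their frame
counters are aligned by switching the pool lighting off briefly several
times (three dips before the recorded event and one after).  Each camera's
mean-luminance series shows the dips as deep negative excursions; matching
the dip onsets across cameras yields integer frame offsets.  Sub-frame
synchronization is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LuminanceSeries",
    "SyncResult",
    "SynchronizationError",
    "detect_extinction_events",
    "synchronize",
    "apply_offsets",
]

#: events separated by fewer frames than this fraction of a second merge
DEFAULT_MIN_SEPARATION_S = 0.5
#: robust threshold multiplier: events fall below median - k * MAD
DEFAULT_K = 5.0
#: inter-event gaps must agree across cameras within this many frames
DEFAULT_GAP_TOLERANCE = 2


class SynchronizationError(ValueError):
    """Event lists across cameras cannot be consistently aligned."""


@dataclass
class LuminanceSeries:
    """Per-frame mean luminance (arbitrary units, nominally 0-1) of one camera."""

    camera_id: str
    luminance: np.ndarray
    frame_rate: float = 120.0

    def __post_init__(self):
        self.luminance = np.asarray(self.luminance, dtype=float).reshape(-1)
        if len(self.luminance) < 1:
            raise ValueError("luminance series must have length >= 1")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")


@dataclass
class SyncResult:
    """Integer frame offsets of each camera relative to a reference camera."""

    reference_camera_id: str
    offsets: dict[str, int] = field(default_factory=dict)
    event_frames: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self):
        if self.offsets.get(self.reference_camera_id, 0) != 0:
            raise ValueError("reference camera offset must be 0")


def detect_extinction_events(
    series: LuminanceSeries,
    k: float = DEFAULT_K,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
    min_duration_frames: int = 3,
) -> list[int]:
    """Frames at which the lighting goes out.

    An event is the first frame of a low excursion below
    ``median - k * MAD`` (robust to the bright foreground subject) that
    stays low for at least ``min_duration_frames`` frames — a real
    extinction lasts many frames, whereas single-frame noise spikes can
    cross any percentile threshold.  Excursion onsets closer than
    ``min_separation_s`` to the previous accepted event are suppressed.
    A constant series yields no events.
    """
    lum = series.luminance
    if len(lum) < 10:
        raise ValueError(f"series too short to detect events ({len(lum)} < 10 frames)")
    median = np.median(lum)
    mad = np.median(np.abs(lum - median))
    threshold = median - k * mad
    below = lum < threshold
    if not below.any():
        return []
    onsets = np.flatnonzero(below & ~np.concatenate([[False], below[:-1]]))
    min_sep = int(round(min_separation_s * series.frame_rate))
    events: list[int] = []
    for frame in onsets:
        run = below[frame : frame + min_duration_frames]
        if len(run) < min_duration_frames or not run.all():
            continue
        if not events or frame - events[-1] >= min_sep:
            events.append(int(frame))
    return events


def synchronize(
    event_lists: dict[str, list[int]],
    reference_camera_id: str,
    gap_tolerance: int = DEFAULT_GAP_TOLERANCE,
) -> SyncResult:
    """Align cameras from their detected event frames.

    Every camera must report the same number of events (>= 1); when more
    than four are present the first four are used, matching the
    three-dips-before/one-after protocol.  The offset of camera c is the
    difference between its first event frame and the reference camera's.
    Inter-event gaps must agree across cameras within ``gap_tolerance``
    frames, otherwise the offending cameras are reported.
    """
    if reference_camera_id not in event_lists:
        raise SynchronizationError(f"reference camera {reference_camera_id!r} has no events")
    counts = {cam: len(ev) for cam, ev in event_lists.items()}
    if min(counts.values()) < 1:
        empty = sorted(c for c, n in counts.items() if n == 0)
        raise SynchronizationError(f"cameras with no detected events: {empty}")
    if len(set(counts.values())) > 1:
        raise SynchronizationError(f"mismatched event counts across cameras: {counts}")

    n_use = min(4, next(iter(counts.values())))
    used = {cam: list(ev[:n_use]) for cam, ev in event_lists.items()}
    ref_events = np.asarray(used[reference_camera_id])
    ref_gaps = np.diff(ref_events)
    bad = []
    for cam, ev in used.items():
        gaps = np.diff(np.asarray(ev))
        if len(gaps) and np.any(np.abs(gaps - ref_gaps) > gap_tolerance):
            bad.append(cam)
    if bad:
        raise SynchronizationError(
            f"inter-event gaps inconsistent with reference {reference_camera_id!r} "
            f"beyond {gap_tolerance} frames for cameras: {sorted(bad)}"
        )
    offsets = {cam: int(ev[0] - ref_events[0]) for cam, ev in used.items()}
    return SyncResult(
        reference_camera_id=reference_camera_id, offsets=offsets, event_frames=used
    )


def apply_offsets(tracks: list, sync: SyncResult) -> list:
    """Re-base 2D track frame indices onto the common (reference) clock.

    A track frame f recorded by camera c becomes f - offset[c].  Samples
    that fall before the common clock origin (negative re-based index) are
    dropped (marked invisible).  Accepts and returns
    :class:`~hydromocap.reconstruction.MarkerTrack2D` lists.
    """
    shifted = []
    for track in tracks:
        if track.camera_id not in sync.offsets:
            raise SynchronizationError(f"unknown camera_id {track.camera_id!r} in sync result")
        offset = sync.offsets[track.camera_id]
        new_frames = track.frames - offset
        keep = new_frames >= 0
        shifted.append(
            type(track)(
                camera_id=track.camera_id,
                label=track.label,
                frames=new_frames[keep],
                pixels=track.pixels[keep],
            )
        )
    return shifted
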