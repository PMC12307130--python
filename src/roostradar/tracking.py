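"""Link per-scan roost detections into dispersal tracks.

A dispersal unfolds over several consecutive scans; the chain of detections
belonging to one event is a track, and the track's peak count is the roost
size estimate.  Linking is scan-to-scan: each detection claims the
previous-scan detection it overlaps the most (raw intersection area; IoU is
available as an alternative), ties go to the nearest centroid, matching is
greedy one-to-one in descending overlap so the result is independent of
input order, and detections with no overlap start new tracks.  Tracks never
bridge a gap: no overlap in the immediately previous scan means a new track,
even if a scan two steps back would overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone

from .quantify import Box

__all__ = ["Detection", "Track", "link_detections", "track_peak"]


@dataclass
class Detection:
    """One annotated bounding box on one scan, with its quantified count."""

    timestamp: datetime
    box: Box
    birds: float = 0.0
    cls: str = "clear"
    scan_id: str = ""

    def __post_init__(self) -> None:
        if self.timestamp.tzinfo is None:
            self.timestamp = self.timestamp.replace(tzinfo=timezone.utc)
        if not (self.box.x_min < self.box.x_max and self.box.y_min < self.box.y_max):
            raise ValueError("degenerate bounding box")
        if self.birds < 0:
            raise ValueError("birds must be nonnegative")

    @property
    def centroid(self) -> tuple[float, float]:
        return self.box.centroid


def _intersection_area(a: Box, b: Box) -> float:
    w = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    h = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    return w * h if (w > 0 and h > 0) else 0.0


def _iou(a: Box, b: Box) -> float:
    inter = _intersection_area(a, b)
    union = a.area() + b.area() - inter
    return inter / union if union > 0 else 0.0


@dataclass
class Track:
    """Time-ordered chain of detections from a single dispersal event."""

    track_id: int
    detections: list[Detection] = field(default_factory=list)

    @property
    def date(self):
        return self.detections[0].timestamp.date()

    @property
    def peak_count(self) -> float:
        return max(d.birds for d in self.detections)

    @property
    def first_centroid(self) -> tuple[float, float]:
        return self.detections[0].centroid

    @property
    def contaminated(self) -> bool:
        return any(d.cls != "clear" for d in self.detections)

    @property
    def rain_contaminated(self) -> bool:
        return any(d.cls == "rain" for d in self.detections)


def track_peak(track: Track) -> float:
    """Roost-size estimate of a track: the maximum count over its detections."""
    if not track.detections:
        raise ValueError("track is empty")
    return track.peak_count


def link_detections(
    scans: list[list[Detection]],
    overlap: str = "area",
    utc_offset: float = 0.0,
) -> list[Track]:
    """Group one day's detections, presented scan by scan, into tracks.

    ``scans`` must be time-ordered lists of detections, all from one local
    calendar day (``utc_offset`` shifts timestamps before the day check).
    ``overlap`` selects the matching metric: raw intersection "area"
    (default) or "iou".
    """
    if overlap not in ("area", "iou"):
        raise ValueError("overlap must be 'area' or 'iou'")
    metric = _intersection_area if overlap == "area" else _iou
    dates = {
        (d.timestamp + timedelta(hours=utc_offset)).date()
        for group in scans
        for d in group
    }
    if len(dates) > 1:
        raise ValueError(f"detections span multiple days: {sorted(dates)}")

    tracks: list[Track] = []
    prev_assignment: dict[int, Track] = {}   # index into previous scan group
    prev_group: list[Detection] = []
    for group in scans:
        if not group:
            prev_assignment, prev_group = {}, []
            continue
        candidates = []
        for ni, det in enumerate(group):
            for pi, prev in enumerate(prev_group):
                a = metric(det.box, prev.box)
                if a > 0:
                    dx = det.centroid[0] - prev.centroid[0]
                    dy = det.centroid[1] - prev.centroid[1]
                    candidates.append((a, math.hypot(dx, dy), ni, pi))
        # greedy one-to-one: largest overlap first, nearest centroid on ties
        candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
        new_assignment: dict[int, Track] = {}
        taken_prev: set[int] = set()
        matched_new: set[int] = set()
        for a, dist, ni, pi in candidates:
            if ni in matched_new or pi in taken_prev:
                continue
            track = prev_assignment[pi]
            track.detections.append(group[ni])
            new_assignment[ni] = track
            matched_new.add(ni)
            taken_prev.add(pi)
        for ni, det in enumerate(group):
            if ni not in matched_new:
                track = Track(track_id=len(tracks), detections=[det])
                tracks.append(track)
                new_assignment[ni] = track
        prev_assignment, prev_group = new_assignment, list(group)
    return tracks
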