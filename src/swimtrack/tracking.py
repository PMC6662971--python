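"""Detection-to-track linking with minimum-cost (Munkres) assignment.

Per frame, active track heads are matched to new detections by solving
the rectangular assignment problem on Euclidean centroid distances
(``scipy.optimize.linear_sum_assignment``); links longer than the gate
are dissolved afterwards. Tracks terminate immediately on a missed
frame — there is no gap closing and no motion model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .segmentation import Detection

__all__ = [
    "Track",
    "Assignment",
    "SpeedSeries",
    "assign_detections",
    "build_tracks",
    "filter_short_tracks",
    "instantaneous_speeds",
]

DEFAULT_MAX_LINK_DISTANCE = 150.0
DEFAULT_MIN_TRACK_FRAMES = 50


@dataclass(frozen=True)
class Track:
    """A gap-free chain of detections belonging to one fish."""

    track_id: int
    detections: list[Detection]
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        frames = [d.frame_index for d in self.detections]
        if frames != list(range(self.start_frame, self.end_frame + 1)):
            raise ValueError("track frames must be consecutive and match bounds")

    def __len__(self) -> int:
        return self.end_frame - self.start_frame + 1

    @property
    def centroids(self) -> np.ndarray:
        """(N, 2) array of (x, y) centroids in frame order."""
        return np.array([d.centroid for d in self.detections], dtype=float)


@dataclass(frozen=True)
class Assignment:
    pairs: list[tuple[int, int]]
    unmatched_tracks: list[int]
    unmatched_detections: list[int]
    total_cost: float


@dataclass(frozen=True)
class SpeedSeries:
    """Per-step centroid displacements of one track, in pixels/frame."""

    track_id: int
    speeds: np.ndarray
    fps: float
    pixel_scale: float | None = None

    def mm_per_s(self) -> np.ndarray:
        if self.pixel_scale is None:
            raise ValueError("no pixel_scale calibration available")
        return self.speeds * self.fps * self.pixel_scale


def assign_detections(
    track_heads: list[tuple[float, float]],
    detections: list[tuple[float, float]],
    max_link_distance: float = DEFAULT_MAX_LINK_DISTANCE,
) -> Assignment:
    """Optimal one-to-one matching of track heads to detection centroids.

    Minimizes total Euclidean distance; any solved pair whose distance
    exceeds ``max_link_distance`` is dissolved into the unmatched sets.
    """
    if max_link_distance <= 0:
        raise ValueError("max_link_distance must be positive")
    if not track_heads or not detections:
        return Assignment(
            pairs=[],
            unmatched_tracks=list(range(len(track_heads))),
            unmatched_detections=list(range(len(detections))),
            total_cost=0.0,
        )
    cost = cdist(np.asarray(track_heads, float), np.asarray(detections, float))
    rows, cols = linear_sum_assignment(cost)
    pairs = []
    total = 0.0
    for r, c in sorted(zip(rows.tolist(), cols.tolist())):
        if cost[r, c] <= max_link_distance:
            pairs.append((r, c))
            total += float(cost[r, c])
    matched_t = {r for r, _ in pairs}
    matched_d = {c for _, c in pairs}
    return Assignment(
        pairs=pairs,
        unmatched_tracks=[i for i in range(len(track_heads)) if i not in matched_t],
        unmatched_detections=[
            j for j in range(len(detections)) if j not in matched_d
        ],
        total_cost=total,
    )


def build_tracks(
    detections_by_frame: list[list[Detection]],
    max_link_distance: float = DEFAULT_MAX_LINK_DISTANCE,
) -> list[Track]:
    """Link per-frame detections into tracks.

    Matched tracks extend; unmatched detections spawn new tracks;
    unmatched tracks terminate immediately. Track ids follow creation
    order.
    """
    finished: list[tuple[int, list[Detection]]] = []
    active: list[tuple[int, list[Detection]]] = []
    next_id = 0
    for dets in detections_by_frame:
        heads = [t[1][-1].centroid for t in active]
        centroids = [d.centroid for d in dets]
        assn = assign_detections(heads, centroids, max_link_distance)
        still_active: list[tuple[int, list[Detection]]] = []
        for ti, di in assn.pairs:
            active[ti][1].append(dets[di])
            still_active.append(active[ti])
        for ti in assn.unmatched_tracks:
            finished.append(active[ti])
        for di in assn.unmatched_detections:
            tr = (next_id, [dets[di]])
            next_id += 1
            still_active.append(tr)
        # keep deterministic creation/extension order by track id
        active = sorted(still_active, key=lambda t: t[0])
    finished.extend(active)
    finished.sort(key=lambda t: t[0])
    return [
        Track(
            track_id=tid,
            detections=chain,
            start_frame=chain[0].frame_index,
            end_frame=chain[-1].frame_index,
        )
        for tid, chain in finished
    ]


def filter_short_tracks(
    tracks: list[Track], min_frames: int = DEFAULT_MIN_TRACK_FRAMES
) -> list[Track]:
    """Drop tracks shorter than ``min_frames`` (false-track removal)."""
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    return [t for t in tracks if len(t) >= min_frames]


def instantaneous_speeds(
    track: Track, fps: float, pixel_scale: float | None = None
) -> SpeedSeries:
    """Frame-to-frame centroid displacement, in pixels/frame."""
    if len(track) < 2:
        raise ValueError("track must span at least 2 frames")
    c = track.centroids
    speeds = np.hypot(*(np.diff(c, axis=0).T))
    return SpeedSeries(
        track_id=track.track_id, speeds=speeds, fps=fps, pixel_scale=pixel_scale
    )
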