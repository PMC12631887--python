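"""Frame-to-frame object tracking and motility metrics.

Tracking is greedy mutual-nearest-neighbor linking between consecutive
frames: a detection in frame t links to a detection in frame t+1 only
when each is the other's nearest neighbor and their distance is within
the gate (default 15 px/frame).  Unmatched detections start new tracks;
there is no gap closing, so an object that disappears for one frame
reappears as a new track.  A Hungarian (optimal-assignment) linker is
available as an option.

Motility metrics per track (>= 2 points):

* speed           — mean Euclidean step length / frame interval (px/s)
* directionality  — net displacement / total path length, in [0, 1];
                    1 for straight co-directed motion, 0 for a closed
                    trajectory
* net displacement— Euclidean distance start -> end (px)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist


@dataclass
class Track:
    track_id: int
    points: list[tuple[int, float, float]] = field(default_factory=list)  # (frame, row, col)
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        frames = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be strictly increasing")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def coords(self) -> np.ndarray:
        return np.array([(r, c) for _, r, c in self.points], dtype=float)


@dataclass
class MotilityMetrics:
    track_id: int
    speed_px_s: float
    directionality: float
    net_displacement_px: float
    n_points: int


def link_tracks(
    centroids_per_frame: list[np.ndarray],
    max_gate_px: float = 15.0,
    frame_interval_s: float = 1.0,
    method: str = "greedy",
) -> list[Track]:
    """Link per-frame centroid lists into tracks.

    ``centroids_per_frame`` is a list (one entry per frame, empty frames
    allowed) of ``(n_i, 2)`` arrays of (row, col) positions.
    """
    if len(centroids_per_frame) < 2:
        raise ValueError("need at least 2 frames to link")
    if method not in ("greedy", "hungarian"):
        raise ValueError("method must be 'greedy' or 'hungarian'")
    tracks: list[Track] = []
    active: dict[int, int] = {}  # detection index in current frame -> track index

    def _new_track(frame: int, pos) -> int:
        tracks.append(
            Track(len(tracks), [(frame, float(pos[0]), float(pos[1]))], frame_interval_s)
        )
        return len(tracks) - 1

    prev = np.asarray(centroids_per_frame[0], dtype=float).reshape(-1, 2)
    active = {i: _new_track(0, prev[i]) for i in range(len(prev))}
    for t in range(1, len(centroids_per_frame)):
        cur = np.asarray(centroids_per_frame[t], dtype=float).reshape(-1, 2)
        links: dict[int, int] = {}  # cur index -> prev index
        if len(prev) and len(cur):
            dist = cdist(prev, cur)
            if method == "greedy":
                nearest_cur = dist.argmin(axis=1)
                nearest_prev = dist.argmin(axis=0)
                for i in range(len(prev)):
                    j = nearest_cur[i]
                    if nearest_prev[j] == i and dist[i, j] <= max_gate_px:
                        links[j] = i
            else:
                rows, cols = linear_sum_assignment(dist)
                for i, j in zip(rows, cols):
                    if dist[i, j] <= max_gate_px:
                        links[j] = i
        new_active: dict[int, int] = {}
        for j in range(len(cur)):
            if j in links and links[j] in active:
                k = active[links[j]]
                tracks[k].points.append((t, float(cur[j, 0]), float(cur[j, 1])))
                new_active[j] = k
            else:
                new_active[j] = _new_track(t, cur[j])
        prev, active = cur, new_active
    return tracks


def motility_metrics(track: Track) -> MotilityMetrics:
    """Speed, directional persistence, and net displacement of one track.

    Single-point tracks have undefined metrics, reported as NaN.
    """
    n = track.n_points
    if n < 2:
        return MotilityMetrics(track.track_id, float("nan"), float("nan"), float("nan"), n)
    xy = track.coords()
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    path = float(steps.sum())
    net = float(np.linalg.norm(xy[-1] - xy[0]))
    speed = float(steps.mean()) / track.frame_interval_s
    directionality = net / path if path > 0 else 0.0
    return MotilityMetrics(track.track_id, speed, min(directionality, 1.0), net, n)
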