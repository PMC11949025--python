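"""Frame-to-frame object linking and motility metrics.

Objects (nuclei or whole cells) segmented in each frame are linked across
time by optimal bipartite assignment on centroid distance, with a hard
distance gate and short-gap bridging by constant-velocity prediction.  Per
track the module reports path length, net displacement, mean speed and
directional processivity (the straightness index D/L).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment

__all__ = ["Track", "link_tracks", "speed_series", "processivity", "frame_centroids"]


@dataclass
class Track:
    """A time-indexed centroid trajectory of one object.

    Coordinates are (z, y, x) in micrometres.  ``frames`` are strictly
    increasing frame indices; ``times`` the corresponding hours.
    """

    track_id: int
    frames: np.ndarray
    points: np.ndarray  # (n, 3) μm
    times: Optional[np.ndarray] = None  # hours
    labels: Optional[np.ndarray] = None  # per-frame segmentation label ids

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.points = np.asarray(self.points, dtype=float).reshape(len(self.frames), -1)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frames must be strictly increasing")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def step_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def path_length(self) -> float:
        """Total arc length L of the trajectory (μm)."""
        return float(self.step_lengths.sum())

    @property
    def net_displacement(self) -> float:
        """Straight-line start-to-end distance D (μm); D <= L always."""
        if len(self) < 2:
            return 0.0
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    def mean_speed(self, frame_interval: float) -> float:
        s = speed_series(self, frame_interval)
        return float(s.mean()) if s.size else 0.0


def processivity(track: Track) -> float:
    """Directional processivity: straightness index rho = D / L in [0, 1].

    1 for perfectly vectored movement, 0 for a trajectory that returns to its
    start; by convention 0 when the path length is 0.
    """
    L = track.path_length
    if L == 0.0:
        return 0.0
    return track.net_displacement / L


def speed_series(track: Track, frame_interval: float) -> np.ndarray:
    """Per-step speeds in μm/h: step distance over elapsed time.

    A singleton track yields an empty series.
    """
    if len(track) < 2:
        return np.empty(0)
    dt = np.diff(track.frames) * float(frame_interval)
    return track.step_lengths / dt


def frame_centroids(labels: np.ndarray, voxel_size: Sequence[float]):
    """Centroids (μm, z/y/x) and label ids of every object in a label volume."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return np.empty((0, 3)), ids
    coms = ndi.center_of_mass(np.ones_like(labels, dtype=np.uint8), labels, ids)
    return np.asarray(coms, dtype=float) * np.asarray(voxel_size, dtype=float), ids


@dataclass
class _Live:
    track_id: int
    frames: list
    points: list
    labels: list
    missed: int = 0

    def predict(self, frame: int) -> np.ndarray:
        # constant-velocity prediction across any bridged gap
        if len(self.points) >= 2:
            v = (self.points[-1] - self.points[-2]) / max(self.frames[-1] - self.frames[-2], 1)
            return self.points[-1] + v * (frame - self.frames[-1])
        return self.points[-1]


def link_tracks(
    label_movie: np.ndarray,
    voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
    frame_interval: float = 1.0,
    max_gate: float = 15.0,
    max_gap: int = 1,
) -> list[Track]:
    """Link a ``(t, z, y, x)`` label movie into centroid tracks.

    Assignments between consecutive frames minimise total centroid distance
    (optimal bipartite assignment); links beyond ``max_gate`` μm are
    forbidden.  Unmatched detections start new tracks; a track missing for up
    to ``max_gap`` consecutive frames is bridged by constant-velocity
    prediction, after which it terminates.
    """
    label_movie = np.asarray(label_movie)
    if label_movie.ndim != 4 or label_movie.shape[0] < 2:
        raise ValueError("label_movie must be (t, z, y, x) with >= 2 frames")
    n_frames = label_movie.shape[0]
    live: list[_Live] = []
    done: list[_Live] = []
    next_id = 0
    BIG = 1e9

    for t in range(n_frames):
        pts, ids = frame_centroids(label_movie[t], voxel_size)
        n_det, n_trk = len(pts), len(live)
        matched_det = np.zeros(n_det, dtype=bool)
        if n_det and n_trk:
            preds = np.stack([trk.predict(t) for trk in live])
            cost = np.linalg.norm(preds[:, None, :] - pts[None, :, :], axis=2)
            cost = np.where(cost <= max_gate, cost, BIG)
            rows, cols = linear_sum_assignment(cost)
            matched_trk = np.zeros(n_trk, dtype=bool)
            for r, c in zip(rows, cols):
                if cost[r, c] >= BIG:
                    continue
                trk = live[r]
                trk.frames.append(t)
                trk.points.append(pts[c])
                trk.labels.append(int(ids[c]))
                trk.missed = 0
                matched_trk[r] = True
                matched_det[c] = True
        else:
            matched_trk = np.zeros(n_trk, dtype=bool)

        still_live = []
        for r, trk in enumerate(live):
            if matched_trk[r]:
                still_live.append(trk)
            else:
                trk.missed += 1
                if trk.missed > max_gap:
                    done.append(trk)
                else:
                    still_live.append(trk)
        live = still_live

        for c in range(n_det):
            if not matched_det[c]:
                live.append(
                    _Live(next_id, [t], [pts[c]], [int(ids[c])])
                )
                next_id += 1

    done.extend(live)
    done.sort(key=lambda trk: trk.track_id)
    tracks = []
    for trk in done:
        frames = np.asarray(trk.frames)
        tracks.append(
            Track(
                trk.track_id,
                frames,
                np.asarray(trk.points),
                times=frames * float(frame_interval),
                labels=np.asarray(trk.labels),
            )
        )
    return tracks
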