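"""Single-cell random-migration analysis.

Links per-frame centroid detections into tracks by greedy nearest-neighbor
assignment and computes the standard motility statistics for adherent
fibroblasts: total travel length, net displacement, mean speed, and
directionality (net / total, in [0, 1]); plus origin-translated "sun plot"
coordinates for track overlays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "TrackMetrics",
    "link_centroids",
    "track_metrics",
    "metrics_table",
    "sunplot_coords",
]


@dataclass
class Track:
    """Timestamped centroid path of one tracked cell."""

    cell_id: int
    positions: np.ndarray  # (n, 2) of (x, y) px
    timestamps: np.ndarray  # minutes, strictly increasing

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.positions) < 2:
            raise ValueError("a track needs at least 2 positions")
        if len(self.positions) != len(self.timestamps):
            raise ValueError("positions and timestamps must align")
        if not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class TrackMetrics:
    """Motility statistics of one track."""

    cell_id: int
    total_path_length: float  # px
    net_displacement: float  # px
    mean_speed: float  # px/min
    directionality: float  # net / total, in [0, 1]; 0 when total is 0


def track_metrics(track: Track) -> TrackMetrics:
    """Total path length, net displacement, mean speed, directionality."""
    steps = np.linalg.norm(np.diff(track.positions, axis=0), axis=1)
    total = float(steps.sum())
    net = float(np.linalg.norm(track.positions[-1] - track.positions[0]))
    elapsed = float(track.timestamps[-1] - track.timestamps[0])
    return TrackMetrics(
        cell_id=track.cell_id,
        total_path_length=total,
        net_displacement=net,
        mean_speed=total / elapsed if elapsed > 0 else 0.0,
        directionality=net / total if total > 0 else 0.0,
    )


def metrics_table(tracks: list[Track]) -> pd.DataFrame:
    """One row of motility statistics per track."""
    return pd.DataFrame([track_metrics(t).__dict__ for t in tracks])


def link_centroids(
    frames: list[np.ndarray],
    max_disp: float,
    frame_interval_min: float = 10.0,
    min_track_length: int = 10,
) -> list[Track]:
    """Greedy nearest-neighbor linking of per-frame centroid sets.

    Each frame is an (n_i, 2) array of (x, y) detections.  Links are made
    greedily in order of increasing distance with per-frame exclusivity;
    candidate links longer than ``max_disp`` are not made, and unlinked
    detections start new tracks.  Tracks spanning fewer than
    ``min_track_length`` frames are dropped.
    """
    if len(frames) < 2:
        raise ValueError("linking needs at least 2 frames")
    frames = [np.asarray(f, dtype=float).reshape(-1, 2) for f in frames]
    # active track -> index of its last detection in the previous frame
    paths: list[list[tuple[int, np.ndarray]]] = [
        [(0, p)] for p in frames[0]
    ]
    active = list(range(len(paths)))
    for fi in range(1, len(frames)):
        dets = frames[fi]
        links: list[tuple[float, int, int]] = []
        for ai, ti in enumerate(active):
            last = paths[ti][-1][1]
            for di, d in enumerate(dets):
                dist = float(np.hypot(*(d - last)))
                if dist <= max_disp:
                    links.append((dist, ai, di))
        links.sort(key=lambda t: t[0])
        used_a: set[int] = set()
        used_d: set[int] = set()
        next_active: list[int] = []
        for dist, ai, di in links:
            if ai in used_a or di in used_d:
                continue
            used_a.add(ai)
            used_d.add(di)
            paths[active[ai]].append((fi, dets[di]))
            next_active.append(active[ai])
        for di, d in enumerate(dets):  # unlinked detections start new tracks
            if di not in used_d:
                paths.append([(fi, d)])
                next_active.append(len(paths) - 1)
        active = next_active
    tracks = []
    cid = 0
    for path in paths:
        if len(path) < max(min_track_length, 2):
            continue
        fis = np.array([fi for fi, _ in path])
        pos = np.stack([p for _, p in path])
        tracks.append(
            Track(cell_id=cid, positions=pos, timestamps=fis * frame_interval_min)
        )
        cid += 1
    return tracks


def sunplot_coords(tracks: list[Track]) -> pd.DataFrame:
    """Origin-translated paths for a sun plot, long format.

    Every track is translated so its first position is (0, 0); output
    columns: cell_id, step, t_min, x, y.
    """
    if not tracks:
        raise ValueError("need at least one track")
    rows = []
    for t in tracks:
        shifted = t.positions - t.positions[0]
        for k, ((x, y), ts) in enumerate(zip(shifted, t.timestamps)):
            rows.append(
                {"cell_id": t.cell_id, "step": k, "t_min": float(ts), "x": x, "y": y}
            )
    return pd.DataFrame(rows)
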