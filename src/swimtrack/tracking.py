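"""Frame-to-frame linking of point detections into trajectories.

Classic nearest-neighbour linking in the Crocker–Grier spirit: for every
frame an optimal bipartite assignment between active track heads and new
detections is solved exactly (minimum total squared displacement), links
longer than ``max_disp`` are forbidden, unmatched detections open new
tracks, and a track survives up to ``memory`` unmatched frames before it is
terminated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = ["LinkConfig", "Track", "link_detections", "tracks_to_dataframe",
           "track_recovery_score"]

# cost assigned to forbidden pairings; large enough that the assignment
# first maximizes the number of admissible links, then minimizes cost
_BIG = 1.0e12


@dataclass(frozen=True)
class LinkConfig:
    """Linking parameters.

    ``max_disp`` gates the displacement of a single link (um); ``memory`` is
    the number of consecutive unmatched frames a track survives; ``fps``
    converts frame indices to seconds on output.
    """

    max_disp: float = 3.0
    memory: int = 2
    fps: float = 20.0

    def __post_init__(self) -> None:
        if self.max_disp <= 0:
            raise ValueError("max_disp must be positive")
        if self.memory < 0:
            raise ValueError("memory must be non-negative")
        if self.fps <= 0:
            raise ValueError("fps must be positive")


@dataclass
class Track:
    """One linked trajectory; gap frames are simply absent from ``frames``."""

    id: int
    frames: list = field(default_factory=list)
    x: list = field(default_factory=list)
    y: list = field(default_factory=list)
    det_rows: list = field(default_factory=list)  # row indices into the input

    def append(self, frame: int, x: float, y: float, row: int) -> None:
        self.frames.append(frame)
        self.x.append(x)
        self.y.append(y)
        self.det_rows.append(row)

    def __len__(self) -> int:
        return len(self.frames)


def _detections_frame(detections) -> pd.DataFrame:
    df = getattr(detections, "df", detections)
    required = {"frame", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"detections need columns {sorted(required)}")
    return df


def link_detections(detections, config: LinkConfig = LinkConfig()) -> list[Track]:
    """Link detections into tracks.

    ``detections`` is a DataFrame (or :class:`~swimtrack.simulate.DetectionFrameSet`)
    with columns ``frame, x_um, y_um``, ordered by frame.  Per frame pair the
    minimum-total-squared-displacement assignment between active track heads
    and new detections is solved; pairings beyond ``max_disp`` are rejected.
    Ties are broken deterministically by lowest (track id, detection index).
    """
    df = _detections_frame(detections)
    frames = df["frame"].to_numpy()
    if len(frames) and np.any(np.diff(frames) < 0):
        raise ValueError("detections must be ordered by frame")

    tracks: list[Track] = []
    active: list[Track] = []  # sorted by id (append order preserves this)
    for frame, grp in df.groupby("frame", sort=True):
        frame = int(frame)
        # drop heads that exceeded their memory
        active = [t for t in active if frame - t.frames[-1] - 1 <= config.memory]
        pts = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        rows = grp.index.to_numpy()
        matched_det = np.zeros(len(pts), dtype=bool)
        if active and len(pts):
            heads = np.array([[t.x[-1], t.y[-1]] for t in active])
            dist = cdist(heads, pts)
            cost = np.where(dist <= config.max_disp, dist**2, _BIG)
            ri, ci = linear_sum_assignment(cost)
            for i, j in zip(ri, ci):
                if dist[i, j] <= config.max_disp:
                    active[i].append(frame, pts[j, 0], pts[j, 1], int(rows[j]))
                    matched_det[j] = True
        # unmatched detections start new tracks, in input order
        for j in np.flatnonzero(~matched_det):
            t = Track(id=len(tracks))
            t.append(frame, pts[j, 0], pts[j, 1], int(rows[j]))
            tracks.append(t)
            active.append(t)
        active.sort(key=lambda t: t.id)
    return tracks


def tracks_to_dataframe(tracks, fps: float = 20.0) -> pd.DataFrame:
    """Trajectory table with columns ``track_id, frame, t_s, x_um, y_um``."""
    rows = []
    for t in tracks:
        rows.append(
            pd.DataFrame(
                {
                    "track_id": t.id,
                    "frame": np.asarray(t.frames, dtype=np.int64),
                    "t_s": np.asarray(t.frames, dtype=float) / fps,
                    "x_um": t.x,
                    "y_um": t.y,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["track_id", "frame", "t_s", "x_um", "y_um"])
    return pd.concat(rows, ignore_index=True)


def track_recovery_score(tracks, detections) -> float:
    """Fraction of consecutive links that connect the same true swimmer.

    ``detections`` must carry the hidden ``truth_id`` column produced by
    :func:`~swimtrack.simulate.render_detections`.  A link is correct iff
    both endpoints are true detections of the same swimmer.  Returns 1.0
    iff every link matches ground truth.
    """
    df = _detections_frame(detections)
    if "truth_id" not in df.columns:
        raise ValueError("detections carry no truth_id column")
    tracks = list(tracks)
    truth = df["truth_id"].to_numpy()
    n_links = 0
    n_correct = 0
    for t in tracks:
        for a, b in zip(t.det_rows[:-1], t.det_rows[1:]):
            n_links += 1
            ta, tb = truth[a], truth[b]
            if ta >= 0 and ta == tb:
                n_correct += 1
    if n_links == 0:
        raise ValueError("no links to score")
    return n_correct / n_links
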