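"""Trajectory quality-control filters.

Two filter dialects are used depending on the imaging environment.  In bulk
fluid, trajectories are removed when their mean speed is below 10 um/s, the
net displacement below 5 um, the duration below 2 s, or when they are highly
curved.  In agar, where cells are slower and runs are interrupted by the
meshwork, only very short (< 1.5 s) and very low-displacement (< 1 um)
trajectories are removed.  A trajectory is removed as soon as it violates
any active rule (OR semantics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["QCRuleSet", "straightness", "trajectory_metrics", "filter_trajectories"]

TRAJ_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]


@dataclass(frozen=True)
class QCRuleSet:
    """Active thresholds; ``None`` disables a rule."""

    min_mean_speed: float | None  # um/s
    min_displacement: float | None  # um, net end-to-end
    min_duration: float | None  # s
    min_straightness: float | None  # dimensionless, in [0, 1]
    dialect: str

    def __post_init__(self) -> None:
        for v in (self.min_mean_speed, self.min_displacement, self.min_duration,
                  self.min_straightness):
            if v is not None and v < 0:
                raise ValueError("thresholds must be non-negative")

    @classmethod
    def bulk(cls, min_mean_speed=10.0, min_displacement=5.0, min_duration=2.0,
             min_straightness=0.5) -> "QCRuleSet":
        """Bulk-fluid cascade: all four rules active."""
        return cls(min_mean_speed, min_displacement, min_duration,
                   min_straightness, dialect="bulk")

    @classmethod
    def agar(cls, min_duration=1.5, min_displacement=1.0) -> "QCRuleSet":
        """Agar cascade: duration and displacement only."""
        return cls(None, min_displacement, min_duration, None, dialect="agar")


def straightness(xy) -> float:
    """Net end-to-end displacement over total path length, in [0, 1].

    1 for a straight constant-heading path, 0 for a closed loop.  A path of
    zero length (a perfectly stationary cell) is returned as 0: it has no
    direction to be straight in, and the displacement rule removes it anyway.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or len(xy) < 2:
        raise ValueError("straightness needs at least two points")
    path = float(np.linalg.norm(np.diff(xy, axis=0), axis=1).sum())
    if path == 0.0:
        return 0.0
    net = float(np.linalg.norm(xy[-1] - xy[0]))
    return net / path


def trajectory_metrics(traj: pd.DataFrame) -> dict:
    """Per-trajectory QC metrics: mean speed, net displacement, duration,
    straightness.  Mean speed is total path length over elapsed time, from
    raw frame-to-frame displacements (no smoothing)."""
    t = traj["t_s"].to_numpy(dtype=float)
    xy = traj[["x_um", "y_um"]].to_numpy(dtype=float)
    elapsed = t[-1] - t[0] if len(t) > 1 else 0.0
    path = float(np.linalg.norm(np.diff(xy, axis=0), axis=1).sum()) if len(xy) > 1 else 0.0
    return {
        "mean_speed": path / elapsed if elapsed > 0 else 0.0,
        "displacement": float(np.linalg.norm(xy[-1] - xy[0])) if len(xy) > 1 else 0.0,
        "duration": elapsed,
        "straightness": straightness(xy) if len(xy) > 1 else 0.0,
    }


def filter_trajectories(trajs: pd.DataFrame, rules: QCRuleSet):
    """Split a trajectory table into (kept, removals).

    ``trajs`` has columns ``track_id, frame, t_s, x_um, y_um``.  Returns the
    kept sub-table (rows untouched) and a removal report DataFrame with
    columns ``track_id, reason`` tagging each removed trajectory with the
    first violated rule.
    """
    kept_ids = []
    removed = []
    for tid, g in trajs.groupby("track_id", sort=True):
        m = trajectory_metrics(g)
        reason = None
        if rules.min_mean_speed is not None and m["mean_speed"] < rules.min_mean_speed:
            reason = "mean_speed"
        elif rules.min_displacement is not None and m["displacement"] < rules.min_displacement:
            reason = "displacement"
        elif rules.min_duration is not None and m["duration"] < rules.min_duration:
            reason = "duration"
        elif rules.min_straightness is not None and m["straightness"] < rules.min_straightness:
            reason = "straightness"
        if reason is None:
            kept_ids.append(tid)
        else:
            removed.append({"track_id": tid, "reason": reason})
    kept = trajs[trajs["track_id"].isin(kept_ids)].copy()
    report = pd.DataFrame(removed, columns=["track_id", "reason"])
    return kept, report
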