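"""Run / trap segmentation of agar trajectories.

A cell swimming through semisolid agar alternates between directed runs and
near-immobile confinement events in the meshwork ("traps").  Segmentation
uses two conditions: (1) every timepoint whose instantaneous speed is below
a threshold (default 7 um/s) is a trap; (2) two consecutive traps whose
spatial endpoints are closer than a merge distance (default 2 um) are fused
into one trap, relabelling everything in between — a cell that jiggles in
place between two confinement events never really escaped.  Condition (2)
is iterated to a fixed point so the result does not depend on merge order.
All remaining timepoints are runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SegmentationParams",
    "PhaseLabeling",
    "instantaneous_speed",
    "segment_runs",
    "run_episode_stats",
]


@dataclass(frozen=True)
class SegmentationParams:
    speed_threshold: float = 7.0  # um/s; below this a timepoint is a trap
    merge_distance: float = 2.0  # um; closer trap endpoints merge
    speed_window: int = 1  # finite-difference half-window, frames

    def __post_init__(self) -> None:
        if self.speed_threshold <= 0 or self.merge_distance <= 0:
            raise ValueError("speed_threshold and merge_distance must be positive")
        if self.speed_window < 1:
            raise ValueError("speed_window must be at least 1")


@dataclass
class PhaseLabeling:
    """Per-timepoint run/trap labels plus the episode decomposition."""

    labels: np.ndarray  # "run" | "trap" per timepoint
    run_episodes: list  # [(start_idx, end_idx)] inclusive
    trap_episodes: list  # [(start_idx, end_idx, entry_xy, exit_xy)]

    @property
    def run_fraction(self) -> float:
        return float(np.mean(self.labels == "run"))

    def to_dataframe(self, track_id=0, frames=None) -> pd.DataFrame:
        n = len(self.labels)
        return pd.DataFrame(
            {
                "track_id": track_id,
                "frame": np.arange(n) if frames is None else np.asarray(frames),
                "phase": self.labels,
            }
        )


def instantaneous_speed(t, xy, window: int = 1) -> np.ndarray:
    """Per-timepoint speed (um/s) by central finite differences.

    Interior points use a symmetric window of ``window`` frames on each
    side; the first/last ``window`` points fall back to one-sided
    differences over the same span.  Output length equals input length.
    """
    t = np.asarray(t, dtype=float)
    xy = np.asarray(xy, dtype=float)
    n = len(t)
    if n < 2:
        raise ValueError("need at least two points to estimate speed")
    if n < window + 1:
        raise ValueError("trajectory shorter than the speed window")
    w = int(window)
    lo = np.clip(np.arange(n) - w, 0, n - 1)
    hi = np.clip(np.arange(n) + w, 0, n - 1)
    disp = np.linalg.norm(xy[hi] - xy[lo], axis=1)
    dt = t[hi] - t[lo]
    return disp / dt


def _episodes(mask: np.ndarray) -> list:
    """Contiguous True stretches of ``mask`` as (start, end) inclusive."""
    out = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def segment_runs(t, xy, params: SegmentationParams = SegmentationParams()) -> PhaseLabeling:
    """Two-pass run/trap segmentation (see module docstring).

    Pass 1 marks timepoints with speed below ``params.speed_threshold`` as
    traps.  Pass 2 merges consecutive traps whose endpoint/startpoint
    distance is below ``params.merge_distance``, iterating to a fixed
    point.  Pass 2 only ever converts run timepoints into trap timepoints.
    """
    t = np.asarray(t, dtype=float)
    xy = np.asarray(xy, dtype=float)
    speed = instantaneous_speed(t, xy, params.speed_window)
    trap = speed < params.speed_threshold

    changed = True
    while changed:
        changed = False
        eps = _episodes(trap)
        for (s1, e1), (s2, e2) in zip(eps[:-1], eps[1:]):
            gap = np.linalg.norm(xy[s2] - xy[e1])
            if gap < params.merge_distance:
                trap[e1 : s2 + 1] = True
                changed = True
        # recompute episodes after a full sweep; repeat until stable

    labels = np.where(trap, "trap", "run").astype(object)
    run_eps = _episodes(~trap)
    trap_eps = [(s, e, xy[s].copy(), xy[e].copy()) for s, e in _episodes(trap)]
    return PhaseLabeling(labels=labels, run_episodes=run_eps, trap_episodes=trap_eps)


def run_episode_stats(
    labeling: PhaseLabeling,
    t,
    xy,
    speed_threshold: float = 7.0,
) -> tuple[pd.DataFrame, dict]:
    """Per-run-episode statistics and their pooled summary.

    For each run episode the mean speed, duration and net displacement are
    computed.  The mean speed is path length over elapsed time counting
    only frame-to-frame steps at or above ``speed_threshold``: the
    windowed speed that defines the run/trap labels smears across phase
    boundaries, so confinement events shorter than the smoothing window
    survive inside run episodes as near-zero steps, and advancement below
    the trap threshold is unresolved confinement rather than running.
    Returns ``(per_episode_df, pooled)`` where ``pooled`` has keys
    ``mean, sem, n``; zero run episodes give an empty frame, not an error.

    The pooled mean weights each episode by its running time, i.e. it
    estimates the mean instantaneous speed during runs.  An unweighted mean
    over episodes would overweight fast modes, whose runs are interrupted
    more often per unit time (trap encounters scale with speed), and is
    available by pooling ``per_episode_df`` directly.  The SEM uses the
    weighted variance with the Kish effective sample size.
    """
    t = np.asarray(t, dtype=float)
    xy = np.asarray(xy, dtype=float)
    if len(labeling.labels) != len(t):
        raise ValueError("labeling does not match trajectory length")
    rows = []
    weights = []
    for k, (s, e) in enumerate(labeling.run_episodes):
        if e > s:
            steps = np.linalg.norm(np.diff(xy[s : e + 1], axis=0), axis=1)
            dts = np.diff(t[s : e + 1])
            moving = steps / dts >= speed_threshold
            if moving.any():
                mean_speed = float(steps[moving].sum() / dts[moving].sum())
                weights.append(float(dts[moving].sum()))
            else:
                mean_speed = float(steps.sum() / dts.sum())
                weights.append(float(dts.sum()))
        else:
            # single-point episode: fall back to the local speed estimate
            mean_speed = float(instantaneous_speed(t, xy)[s])
            weights.append(float(np.median(np.diff(t))))
        rows.append(
            {
                "episode_idx": k,
                "start_frame": s,
                "end_frame": e,
                "duration_s": float(t[e] - t[s]),
                "displacement_um": float(np.linalg.norm(xy[e] - xy[s])),
                "mean_speed_um_s": mean_speed,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["episode_idx", "start_frame", "end_frame", "duration_s",
                 "displacement_um", "mean_speed_um_s"],
    )
    df["weight_s"] = weights
    if len(df) == 0:
        pooled = {"mean": np.nan, "sem": np.nan, "n": 0}
    else:
        pooled = pooled_speed(df["mean_speed_um_s"].to_numpy(), np.asarray(weights))
    return df, pooled


def pooled_speed(values: np.ndarray, weights: np.ndarray) -> dict:
    """Duration-weighted pooled mean speed with weighted SEM.

    SEM = weighted s.d. / sqrt(n_eff) with the Kish effective sample size
    ``n_eff = (sum w)^2 / sum w^2``.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    w = weights / weights.sum()
    mean = float(np.sum(w * values))
    if len(values) > 1:
        var = float(np.sum(w * (values - mean) ** 2))
        n_eff = 1.0 / float(np.sum(w**2))
        sem = np.sqrt(var / max(n_eff - 1.0, 1.0))
    else:
        sem = float("nan")
    return {"mean": mean, "sem": float(sem), "n": int(len(values))}


def segment_table(
    trajs: pd.DataFrame, params: SegmentationParams = SegmentationParams()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment every trajectory in a table.

    Returns ``(labels, episodes)``: per-timepoint phase labels
    (``track_id, frame, phase``) and per-episode records
    (``track_id, episode_idx, kind, start_frame, end_frame, mean_speed_um_s``).
    Trajectories shorter than the speed window are skipped with a warning.
    """
    label_frames = []
    episode_rows = []
    for tid, g in trajs.groupby("track_id", sort=True):
        t = g["t_s"].to_numpy(dtype=float)
        xy = g[["x_um", "y_um"]].to_numpy(dtype=float)
        if len(t) < params.speed_window + 1:
            warnings.warn(f"track {tid} shorter than speed window; skipped")
            continue
        lab = segment_runs(t, xy, params)
        label_frames.append(lab.to_dataframe(track_id=tid, frames=g["frame"].to_numpy()))
        per_ep, _ = run_episode_stats(lab, t, xy, speed_threshold=params.speed_threshold)
        for _, row in per_ep.iterrows():
            episode_rows.append(
                {
                    "track_id": tid,
                    "episode_idx": int(row["episode_idx"]),
                    "kind": "run",
                    "start_frame": int(row["start_frame"]),
                    "end_frame": int(row["end_frame"]),
                    "mean_speed_um_s": row["mean_speed_um_s"],
                }
            )
        for k, (s, e, _, _) in enumerate(lab.trap_episodes):
            episode_rows.append(
                {
                    "track_id": tid,
                    "episode_idx": k,
                    "kind": "trap",
                    "start_frame": int(s),
                    "end_frame": int(e),
                    "mean_speed_um_s": np.nan,
                }
            )
    labels = (
        pd.concat(label_frames, ignore_index=True)
        if label_frames
        else pd.DataFrame(columns=["track_id", "frame", "phase"])
    )
    episodes = pd.DataFrame(
        episode_rows,
        columns=["track_id", "episode_idx", "kind", "start_frame", "end_frame",
                 "mean_speed_um_s"],
    )
    return labels, episodes
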