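"""Population speed statistics and mean-square-displacement analysis.

Speeds are summarized per trajectory (mean of frame-wise speeds) and then
over the population (unweighted mean across trajectories, SEM across
trajectories), matching how per-trajectory speed distributions are usually
reported.  A runs-only dialect pools run episodes from the run/trap
segmentation instead, as appropriate in agar where runs and confinement
events alternate.  MSD curves are time-averaged within each trajectory and
ensemble-averaged across trajectories with per-lag pair counts as weights;
the diffusivity is the fitted slope over a lag window divided by 4 (2-D),
with a log-log slope diagnostic to flag ballistic (superdiffusive) curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .run_trap import SegmentationParams, pooled_speed, run_episode_stats, segment_runs

__all__ = [
    "SpeedSummary",
    "MSDCurve",
    "DiffusivityFit",
    "population_speed",
    "compute_msd",
    "estimate_diffusivity",
]


@dataclass
class SpeedSummary:
    """Per-unit mean speeds with population mean +/- SEM."""

    per_unit: np.ndarray  # um/s; per trajectory or per run episode
    mean: float
    sem: float  # NaN when n == 1
    n: int
    dialect: str  # "whole" | "runs"

    def as_row(self) -> dict:
        return {"dialect": self.dialect, "mean_um_s": self.mean,
                "sem_um_s": self.sem, "n": self.n}


@dataclass
class MSDCurve:
    lag_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag_s": self.lag_s, "msd_um2": self.msd_um2, "n_pairs": self.n_pairs}
        )


@dataclass
class DiffusivityFit:
    D: float  # um^2/s
    slope: float  # um^2/s, d MSD / d lag
    loglog_slope: float
    superdiffusive: bool


def _traj_arrays(trajs: pd.DataFrame):
    for tid, g in trajs.groupby("track_id", sort=True):
        yield tid, g["t_s"].to_numpy(dtype=float), g[["x_um", "y_um"]].to_numpy(dtype=float)


def population_speed(
    trajs: pd.DataFrame,
    dialect: str = "whole",
    seg_params: SegmentationParams | None = None,
    point_weighted: bool = False,
) -> SpeedSummary:
    """Population speed summary over a trajectory table.

    ``dialect="whole"``: one mean speed per trajectory (path length over
    elapsed time, turns and stops included), population mean unweighted
    across trajectories and SEM across trajectories;
    ``point_weighted=True`` switches to weighting trajectories by their
    number of frames (non-default alternative).  ``dialect="runs"``:
    trajectories are segmented into run/trap phases and the per-run-episode
    mean speeds are pooled with duration weights (the mean instantaneous
    speed during runs; see :func:`swimtrack.run_trap.run_episode_stats`).
    """
    if trajs is None or len(trajs) == 0:
        raise ValueError("empty trajectory set")
    if dialect not in ("whole", "runs"):
        raise ValueError("dialect must be 'whole' or 'runs'")
    values = []
    weights = []
    for tid, t, xy in _traj_arrays(trajs):
        if len(t) < 2:
            continue
        if dialect == "whole":
            path = float(np.linalg.norm(np.diff(xy, axis=0), axis=1).sum())
            values.append(path / (t[-1] - t[0]))
            weights.append(len(t))
        else:
            params = seg_params or SegmentationParams()
            if len(t) < params.speed_window + 1:
                continue
            lab = segment_runs(t, xy, params)
            per_ep, _ = run_episode_stats(lab, t, xy,
                                          speed_threshold=params.speed_threshold)
            values.extend(per_ep["mean_speed_um_s"].tolist())
            weights.extend(per_ep["weight_s"].tolist())
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("no usable trajectories (or no run episodes)")
    if dialect == "runs":
        pooled = pooled_speed(v, np.asarray(weights, dtype=float))
        return SpeedSummary(per_unit=v, mean=pooled["mean"], sem=pooled["sem"],
                            n=pooled["n"], dialect=dialect)
    if point_weighted:
        w = np.asarray(weights, dtype=float)
        mean = float(np.average(v, weights=w))
    else:
        mean = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")
    return SpeedSummary(per_unit=v, mean=mean, sem=sem, n=len(v), dialect=dialect)


def compute_msd(trajs: pd.DataFrame, max_lag: float) -> MSDCurve:
    """Ensemble mean square displacement up to ``max_lag`` seconds.

    Each trajectory must sit on one shared frame grid (gap frames from
    tracking dropouts are allowed and simply contribute no pairs).  Per
    trajectory the time-averaged (overlapping-window) squared displacement
    is accumulated at each integer frame lag, then the ensemble average
    weights each trajectory by its number of contributing pairs.  Lag 0 is
    included with MSD 0.
    """
    if trajs is None or len(trajs) == 0:
        raise ValueError("empty trajectory set")
    dts = []
    items = []
    for tid, g in trajs.groupby("track_id", sort=True):
        t = g["t_s"].to_numpy(dtype=float)
        f = g["frame"].to_numpy(dtype=np.int64)
        xy = g[["x_um", "y_um"]].to_numpy(dtype=float)
        if len(t) < 2:
            continue
        span = f[-1] - f[0]
        dt_i = (t[-1] - t[0]) / span
        if np.max(np.abs((t - t[0]) - (f - f[0]) * dt_i)) > 1e-6 * max(dt_i, 1.0):
            raise ValueError(f"track {tid} frames and times disagree")
        dense = np.full((span + 1, 2), np.nan)
        dense[f - f[0]] = xy
        dts.append(dt_i)
        items.append(dense)
    if not items:
        raise ValueError("no usable trajectories")
    dt = dts[0]
    if max(abs(d - dt) for d in dts) > 1e-9 * dt:
        raise ValueError("trajectories have inconsistent frame intervals")
    if max_lag < dt:
        raise ValueError("max_lag below one frame interval")
    n_lags = int(np.floor(max_lag / dt + 1e-9))
    sums = np.zeros(n_lags + 1)
    counts = np.zeros(n_lags + 1, dtype=np.int64)
    counts[0] = sum(int(np.isfinite(d[:, 0]).sum()) for d in items)
    for dense in items:
        m = len(dense)
        for k in range(1, min(n_lags, m - 1) + 1):
            d = dense[k:] - dense[:-k]
            sq = np.einsum("ij,ij->i", d, d)
            good = np.isfinite(sq)
            sums[k] += float(sq[good].sum())
            counts[k] += int(good.sum())
    msd = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    return MSDCurve(lag_s=np.arange(n_lags + 1) * dt, msd_um2=msd, n_pairs=counts)


def estimate_diffusivity(
    msd: MSDCurve, fit_range: tuple[float, float] | None = None
) -> DiffusivityFit:
    """Diffusivity from the linear slope of the MSD over a lag window.

    ``fit_range = (lag_min, lag_max)`` in seconds selects the window
    (default: the whole positive-lag curve).  ``D = slope / 4`` in two
    dimensions.  If the log-log slope of the windowed curve exceeds 1.5 the
    motion is flagged as superdiffusive (ballistic-like) and a warning is
    emitted: the diffusive interpretation of the slope then fails.
    """
    lag = msd.lag_s
    val = msd.msd_um2
    if fit_range is None:
        sel = lag > 0
    else:
        lo, hi = fit_range
        sel = (lag >= lo) & (lag <= hi) & (lag > 0)
    if sel.sum() < 2:
        raise ValueError("need at least two lags in the fit window")
    x, y = lag[sel], val[sel]
    slope, _ = np.polyfit(x, y, 1)
    pos = y > 0
    if pos.sum() >= 2:
        ll_slope = float(np.polyfit(np.log(x[pos]), np.log(y[pos]), 1)[0])
    else:
        ll_slope = float("nan")
    superdiffusive = bool(ll_slope > 1.5)
    if superdiffusive:
        warnings.warn(
            "MSD grows superdiffusively (log-log slope "
            f"{ll_slope:.2f} > 1.5); the fitted D is not a diffusivity"
        )
    return DiffusivityFit(
        D=float(slope / 4.0),
        slope=float(slope),
        loglog_slope=ll_slope,
        superdiffusive=superdiffusive,
    )
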