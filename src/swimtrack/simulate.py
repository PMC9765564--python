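"""Synthetic swimmer, detection, division and spreading generators.

Everything the downstream analysis consumes can be generated here with known
ground truth: two-dimensional swimmer paths with per-timepoint mode
(push / pull / wrapped / stop) and phase (run / trap) labels, noisy per-frame
centroid detections, division events with motile or sessile daughters, and
colony-diameter time series for the soft-agar spreading assay.

The swimmer model is a continuous-time Markov chain over the three run modes
and a stop state, discretized on the imaging grid (default 20 frames per
second).  During runs the cell translates at the mode speed scaled by the
viscous slowdown factor and its heading diffuses rotationally; push<->pull
switches reverse the heading (180 degrees plus a small jitter); in agar,
trap encounters fire as a Poisson process along the run path, immobilize the
cell for an exponential dwell, and release it with a fresh random heading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import MODES, EnvironmentProfile, StrainProfile

__all__ = [
    "SwimmerPath",
    "DetectionFrameSet",
    "DivisionRecord",
    "SpreadingSeries",
    "simulate_swimmer",
    "simulate_population",
    "paths_to_dataframe",
    "render_detections",
    "simulate_division_clusters",
    "effective_diffusivity",
    "effective_growth_rate",
    "front_speed",
    "simulate_spreading",
]

#: mm^2/h per um^2/s
_UM2_S_TO_MM2_H = 3600.0 / 1.0e6


# ---------------------------------------------------------------------- #
# containers


@dataclass
class SwimmerPath:
    """Ground-truth path of one swimmer on a uniform time grid."""

    id: int
    times: np.ndarray  # s
    xy: np.ndarray  # (N, 2) um
    mode: np.ndarray  # per-timepoint label in MODES
    phase: np.ndarray  # per-timepoint "run" | "trap"
    dt: float

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.times) > 0) and len(self.times) > 1:
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("positions must be finite")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def path_length(self) -> float:
        """Total arc length, um."""
        return float(np.linalg.norm(np.diff(self.xy, axis=0), axis=1).sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "track_id": self.id,
                "frame": np.arange(len(self.times)),
                "t_s": self.times,
                "x_um": self.xy[:, 0],
                "y_um": self.xy[:, 1],
                "mode": self.mode,
                "phase": self.phase,
            }
        )


@dataclass
class DetectionFrameSet:
    """Per-frame unlabeled point detections (plus hidden truth ids).

    ``df`` has columns ``frame, x_um, y_um, truth_id`` with ``truth_id = -1``
    for false positives; only the first three columns are part of the public
    CSV interface, the truth column exists to score tracking on synthetic
    data.
    """

    df: pd.DataFrame
    fov: tuple[float, float, float, float]
    dt: float

    @property
    def n_frames(self) -> int:
        return 0 if self.df.empty else int(self.df["frame"].max()) + 1


@dataclass(frozen=True)
class DivisionRecord:
    """One division event; exactly two daughters."""

    parent_id: int
    time_h: float
    daughters: tuple[str, str]  # each "motile" | "sessile"
    cluster_id: int | None  # cluster the sessile daughter(s) belong to


@dataclass
class SpreadingSeries:
    """Colony diameter over time in the soft-agar assay."""

    strain: str
    agar_pct: float
    times_h: np.ndarray
    diameter_mm: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.diameter_mm) < -1e-9):
            raise ValueError("colony diameter must be non-decreasing")
        if self.diameter_mm[0] < 0:
            raise ValueError("diameter must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strain": self.strain,
                "agar_pct": self.agar_pct,
                "t_h": self.times_h,
                "diameter_mm": self.diameter_mm,
            }
        )


# ---------------------------------------------------------------------- #
# swimmer paths


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_swimmer(
    strain: StrainProfile,
    env: EnvironmentProfile,
    duration: float,
    dt: float = 0.05,
    seed=None,
    origin=(0.0, 0.0),
) -> SwimmerPath:
    """Simulate one swimmer for ``duration`` seconds at time step ``dt``.

    Mode switching follows the strain's generator matrix at the
    environment's load (rates into pull/wrapped re-split by the wrapped
    propensity); the chain starts from its stationary distribution so time
    averages match the stationary occupancies from the first frame on.
    Identical seeds give identical paths.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if duration > 0 and dt >= duration:
        raise ValueError("dt must be smaller than duration")
    rng = _as_rng(seed)

    n_steps = int(round(duration / dt)) if duration > 0 else 0
    times = np.arange(n_steps + 1) * dt
    xy = np.empty((n_steps + 1, 2))
    xy[0] = origin
    mode_idx = np.empty(n_steps + 1, dtype=np.int64)
    phase = np.full(n_steps + 1, "run", dtype=object)

    Q = strain.generator_matrix(env.load)
    # per-step switch probabilities of the discretized chain; the stationary
    # distribution of I + Q*dt equals that of Q exactly
    P_off = Q * dt
    np.fill_diagonal(P_off, 0.0)
    if P_off.sum(axis=1).max() >= 1.0:
        raise ValueError("dt too large for the configured switch rates")
    speeds = strain.speeds_in(env)
    speed_by_idx = np.array([speeds[m] for m in MODES])
    stop_idx = MODES.index("stop")
    push_idx, pull_idx = MODES.index("push"), MODES.index("pull")

    pi = strain.stationary_distribution(env.load)
    current = int(rng.choice(len(MODES), p=pi))
    theta = rng.uniform(0.0, 2.0 * np.pi)
    rot_sigma = math.sqrt(2.0 * strain.rot_diffusion * dt)
    jitter_rad = math.radians(strain.reversal_jitter_deg)
    trap_per_um = env.trap_rate_per_um
    # exponential dwell discretized as per-frame release (memoryless on the
    # grid, mean dwell exact)
    p_release = dt / env.trap_duration_mean if env.trap_duration_mean > 0 else 1.0
    trapped = False

    for i in range(n_steps):
        mode_idx[i] = current
        if trapped:
            # wedged in the meshwork: no translation, but the motor keeps
            # switching modes (trying to escape), so the chain evolves in
            # real time and the run-mode composition stays stationary
            phase[i] = "trap"
            xy[i + 1] = xy[i]
            if rng.random() < p_release:
                trapped = False
                theta = rng.uniform(0.0, 2.0 * np.pi)  # escape, reoriented
        else:
            v = speed_by_idx[current]
            step = v * dt
            xy[i + 1, 0] = xy[i, 0] + step * math.cos(theta)
            xy[i + 1, 1] = xy[i, 1] + step * math.sin(theta)
            if v > 0.0:
                theta += rot_sigma * rng.standard_normal()
                if trap_per_um > 0.0 and rng.random() < trap_per_um * step:
                    trapped = True
        # mode switch at the end of the step
        u = rng.random()
        acc = 0.0
        nxt = current
        for j in range(len(MODES)):
            p = P_off[current, j]
            if p <= 0.0:
                continue
            acc += p
            if u < acc:
                nxt = j
                break
        if nxt != current:
            if not trapped and {current, nxt} == {push_idx, pull_idx}:
                theta += math.pi + jitter_rad * rng.standard_normal()
            current = nxt

    # final timepoint carries the state reached after the last step
    mode_idx[n_steps] = current
    if trapped:
        phase[n_steps] = "trap"

    return SwimmerPath(
        id=0,
        times=times,
        xy=xy,
        mode=np.array(MODES, dtype=object)[mode_idx],
        phase=phase,
        dt=dt,
    )


def simulate_population(
    n: int,
    strain: StrainProfile,
    env: EnvironmentProfile,
    duration: float,
    dt: float = 0.05,
    seed=None,
    box: tuple[float, float, float, float] | None = None,
) -> list[SwimmerPath]:
    """``n`` independent swimmers with per-path seeds derived from ``seed``.

    With ``box = (xmin, xmax, ymin, ymax)`` the starting positions are drawn
    uniformly in the box; otherwise every path starts at the origin.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n + 1)
    origin_rng = np.random.default_rng(children[0])
    paths = []
    for i in range(n):
        if box is not None:
            xmin, xmax, ymin, ymax = box
            origin = (origin_rng.uniform(xmin, xmax), origin_rng.uniform(ymin, ymax))
        else:
            origin = (0.0, 0.0)
        p = simulate_swimmer(
            strain, env, duration, dt, seed=np.random.default_rng(children[i + 1]),
            origin=origin,
        )
        p.id = i
        paths.append(p)
    return paths


def paths_to_dataframe(paths) -> pd.DataFrame:
    """Stack ground-truth paths into one trajectory table."""
    if not paths:
        return pd.DataFrame(
            columns=["track_id", "frame", "t_s", "x_um", "y_um", "mode", "phase"]
        )
    return pd.concat([p.to_dataframe() for p in paths], ignore_index=True)


# ---------------------------------------------------------------------- #
# detections


def render_detections(
    paths,
    sigma_loc: float = 0.05,
    p_detect: float = 0.97,
    fp_per_frame: float = 0.2,
    fov: tuple[float, float, float, float] | None = None,
    seed=None,
) -> DetectionFrameSet:
    """Emulate per-frame centroid detection of the given paths.

    Each in-view swimmer emits a detection with probability ``p_detect`` at
    its true position plus isotropic Gaussian localization noise of s.d.
    ``sigma_loc`` (um per axis); ``fp_per_frame`` false detections per frame
    (Poisson) are scattered uniformly over the field of view
    ``fov = (xmin, xmax, ymin, ymax)``.  With ``fov=None`` the bounding box
    of all paths plus a 5-um margin is used.
    """
    if sigma_loc < 0:
        raise ValueError("sigma_loc must be non-negative")
    if not 0.0 <= p_detect <= 1.0:
        raise ValueError("p_detect must be a probability")
    paths = list(paths)
    if not paths:
        raise ValueError("no paths to render")
    dt = paths[0].dt
    if any(abs(p.dt - dt) > 1e-12 for p in paths):
        raise ValueError("all paths must share the same time step")
    if fov is None:
        allxy = np.vstack([p.xy for p in paths])
        fov = (
            float(allxy[:, 0].min() - 5.0),
            float(allxy[:, 0].max() + 5.0),
            float(allxy[:, 1].min() - 5.0),
            float(allxy[:, 1].max() + 5.0),
        )
    xmin, xmax, ymin, ymax = fov
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("field of view is empty")

    rng = _as_rng(seed)
    n_frames = max(len(p) for p in paths)
    pos = np.full((n_frames, len(paths), 2), np.nan)
    for j, p in enumerate(paths):
        pos[: len(p), j] = p.xy
    ids = np.array([p.id for p in paths])

    blocks = []
    for f in range(n_frames):
        pts = pos[f]
        alive = np.isfinite(pts[:, 0])
        inview = (
            alive
            & (pts[:, 0] >= xmin)
            & (pts[:, 0] <= xmax)
            & (pts[:, 1] >= ymin)
            & (pts[:, 1] <= ymax)
        )
        det = inview & (rng.random(len(paths)) < p_detect)
        obs = pts[det] + rng.normal(0.0, sigma_loc, size=(int(det.sum()), 2))
        n_fp = rng.poisson(fp_per_frame)
        fp = np.column_stack(
            [rng.uniform(xmin, xmax, n_fp), rng.uniform(ymin, ymax, n_fp)]
        )
        blocks.append(
            pd.DataFrame(
                {
                    "frame": f,
                    "x_um": np.concatenate([obs[:, 0], fp[:, 0]]),
                    "y_um": np.concatenate([obs[:, 1], fp[:, 1]]),
                    "truth_id": np.concatenate(
                        [ids[det], np.full(n_fp, -1, dtype=np.int64)]
                    ),
                }
            )
        )
    df = pd.concat(blocks, ignore_index=True)
    df["frame"] = df["frame"].astype(np.int64)
    df["truth_id"] = df["truth_id"].astype(np.int64)
    return DetectionFrameSet(df=df, fov=fov, dt=dt)


# ---------------------------------------------------------------------- #
# division and clusters


def simulate_division_clusters(
    strain: StrainProfile,
    env: EnvironmentProfile,
    n0: int,
    duration: float,
    seed=None,
    max_cells: int = 200_000,
):
    """Branching process of dividing cells with motile or sessile daughters.

    Every cell divides at the strain's division rate (exponential
    inter-division times).  Divisions happen while the parent is trapped;
    each of the two daughters is independently motile with the strain's
    ``p_motile_daughter`` for the environment.  A sessile daughter joins the
    parent's cluster (or founds one at the division site) and keeps
    dividing, so clusters grow; motile daughters swim off.

    Returns ``(records, summary)``: the list of :class:`DivisionRecord` and
    a DataFrame with columns ``t_h, n_motile, n_sessile, n_clusters,
    largest_cluster`` sampled at every division plus the endpoints.
    """
    if n0 < 1:
        raise ValueError("n0 must be at least 1")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    rng = _as_rng(seed)
    p_motile = strain.motile_daughter_prob(env)
    g = strain.division_rate

    # cell -> cluster id (None = motile); dict keyed by cell id
    cluster_of: dict[int, int | None] = {i: None for i in range(n0)}
    next_cell = n0
    next_cluster = 0
    cluster_sizes: dict[int, int] = {}
    records: list[DivisionRecord] = []
    rows = []

    def snapshot(t: float) -> None:
        n_sessile = sum(1 for c in cluster_of.values() if c is not None)
        rows.append(
            {
                "t_h": t,
                "n_motile": len(cluster_of) - n_sessile,
                "n_sessile": n_sessile,
                "n_clusters": sum(1 for s in cluster_sizes.values() if s > 0),
                "largest_cluster": max(cluster_sizes.values(), default=0),
            }
        )

    snapshot(0.0)
    t = 0.0
    while g > 0 and len(cluster_of) < max_cells:
        rate = g * len(cluster_of)
        t += rng.exponential(1.0 / rate)
        if t > duration:
            break
        parent = list(cluster_of)[rng.integers(len(cluster_of))]
        parent_cluster = cluster_of.pop(parent)
        if parent_cluster is not None:
            cluster_sizes[parent_cluster] -= 1
        states = tuple(
            "motile" if rng.random() < p_motile else "sessile" for _ in range(2)
        )
        rec_cluster: int | None = None
        for st in states:
            if st == "sessile":
                if rec_cluster is None:
                    if parent_cluster is not None:
                        rec_cluster = parent_cluster
                    else:
                        rec_cluster = next_cluster
                        next_cluster += 1
                        cluster_sizes.setdefault(rec_cluster, 0)
                cluster_of[next_cell] = rec_cluster
                cluster_sizes[rec_cluster] += 1
            else:
                cluster_of[next_cell] = None
            next_cell += 1
        records.append(
            DivisionRecord(parent_id=parent, time_h=t, daughters=states,
                           cluster_id=rec_cluster)
        )
        snapshot(t)
    snapshot(duration)
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------- #
# spreading fronts


def effective_diffusivity(strain: StrainProfile, env: EnvironmentProfile) -> float:
    """Run-and-reorient diffusivity ``D = v^2 * tau / 2`` in um^2/s (2-D).

    ``v`` is the stationary mixture mean run speed and ``tau`` the run
    correlation time (inverse reorientation rate, trap encounters included
    in agar).
    """
    v = strain.run_speed_mean(env)
    if v == 0.0:
        return 0.0
    tau = 1.0 / strain.reorientation_rate(env)
    return 0.5 * v * v * tau


def effective_growth_rate(strain: StrainProfile, env: EnvironmentProfile) -> float:
    """Growth rate of the motile subpopulation, 1/h.

    Division only helps the front when daughters swim off, so the division
    rate is discounted by the motile-daughter probability: sessile-cluster
    formation slows spreading without touching the swimming speed.
    """
    return strain.division_rate * strain.motile_daughter_prob(env)


def front_speed(strain: StrainProfile, env: EnvironmentProfile) -> float:
    """Pulled-front (Fisher) speed ``c = 2 sqrt(D_eff * g_eff)`` in mm/h.

    Applied directly to the measured colony diameter, absorbing the
    radius-to-diameter factor into the effective constants.
    """
    d_mm2_h = effective_diffusivity(strain, env) * _UM2_S_TO_MM2_H
    return 2.0 * math.sqrt(d_mm2_h * effective_growth_rate(strain, env))


def simulate_spreading(
    strain: StrainProfile,
    env: EnvironmentProfile,
    duration: float,
    seed=None,
    dt_h: float = 0.25,
    d0_mm: float = 4.0,
    lag_h: float = 2.0,
    noise_mm: float = 0.0,
) -> SpreadingSeries:
    """Colony-diameter time series: flat lag, then a linear front.

    ``diameter(t) = d0 + c * max(t - lag, 0)`` with the front speed ``c``
    from :func:`front_speed`; optional additive Gaussian noise is applied
    and the series is then made non-decreasing (a colony never shrinks).
    A nonmotile strain keeps its inoculation diameter forever.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    times = np.arange(0.0, duration + 0.5 * dt_h, dt_h)
    c = front_speed(strain, env)
    diameter = d0_mm + c * np.clip(times - lag_h, 0.0, None)
    if noise_mm > 0:
        rng = _as_rng(seed)
        diameter = diameter + rng.normal(0.0, noise_mm, size=diameter.shape)
        diameter = np.maximum.accumulate(diameter)
        diameter = np.clip(diameter, 0.0, None)
    return SpreadingSeries(
        strain=strain.name, agar_pct=env.agar_pct, times_h=times, diameter_mm=diameter
    )
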