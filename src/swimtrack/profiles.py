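"""Strain and environment profiles.

A :class:`StrainProfile` holds the generative parameters of one genotype:
run-mode speeds (push / pull / wrapped), the continuous-time Markov switch
rates between the three run modes and the stop state, the wrapped-mode
propensity curve, rotational diffusion, and the division parameters that
drive cluster formation and colony spreading.  An
:class:`EnvironmentProfile` describes one medium: bulk aqueous fluid,
Ficoll-thickened fluid, or semisolid agar with its pore-size range and
trapping statistics.

Default profiles for the wild type, the two single stator knockouts
(``motAB`` missing / ``motCD`` missing), the nonmotile double knockout, and
the standard media ship in ``data/profiles.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

from . import media

__all__ = [
    "MODES",
    "RUN_MODES",
    "CW_MODES",
    "StrainProfile",
    "EnvironmentProfile",
    "load_profiles",
    "load_default_profiles",
    "get_strain",
    "get_environment",
]

#: State space of the mode-switching Markov chain.  ``stop`` is the
#: non-translating state between runs.
MODES: tuple[str, ...] = ("push", "pull", "wrapped", "stop")
RUN_MODES: tuple[str, ...] = ("push", "pull", "wrapped")
#: Modes powered by clockwise flagellar rotation.
CW_MODES: tuple[str, ...] = ("pull", "wrapped")

#: Pore diameter (nm) at which ``trap_rate`` is quoted; the effective
#: encounter rate scales as the inverse mean pore diameter.
REFERENCE_PORE_NM = 1000.0


@dataclass(frozen=True)
class StrainProfile:
    """Generative parameters for one strain."""

    name: str
    #: run speed per mode in bulk fluid, um/s
    mode_speed: Mapping[str, float]
    #: off-diagonal CTMC rates, 1/s: ``switch_rate[from][to]``
    switch_rate: Mapping[str, Mapping[str, float]]
    #: nominal fraction of run time spent pushing (CCW rotation); informational
    ccw_bias: float
    #: (midpoint load cP, steepness / log-width, max) of P(wrapped | CW)
    wrapped_propensity_params: tuple[float, float, float]
    propensity_shape: str = "logistic"
    #: rotational diffusion of the heading during runs, rad^2/s
    rot_diffusion: float = 0.1
    #: division rate, 1/h (doubling time = ln 2 / rate)
    division_rate: float = 0.9
    #: environment label -> probability that a daughter cell is motile
    p_motile_daughter: Mapping[str, float] = field(default_factory=dict)
    #: optional run speeds in agar, um/s; stator remodelling in the meshwork
    #: makes these strain-specific and not derivable from the bulk speeds
    mode_speed_agar: Mapping[str, float] | None = None
    #: s.d. of the heading jitter applied on push<->pull reversals, degrees
    reversal_jitter_deg: float = 15.0

    def __post_init__(self) -> None:
        for m in RUN_MODES:
            if m not in self.mode_speed:
                raise ValueError(f"{self.name}: missing mode speed for {m!r}")
            if self.mode_speed[m] < 0:
                raise ValueError(f"{self.name}: negative speed for {m!r}")
        if self.mode_speed_agar is not None:
            for m in RUN_MODES:
                if self.mode_speed_agar.get(m, 0.0) < 0:
                    raise ValueError(f"{self.name}: negative agar speed for {m!r}")
        for src, row in self.switch_rate.items():
            if src not in MODES:
                raise ValueError(f"{self.name}: unknown mode {src!r} in switch_rate")
            for dst, rate in row.items():
                if dst not in MODES or dst == src:
                    raise ValueError(f"{self.name}: bad transition {src}->{dst}")
                if rate < 0:
                    raise ValueError(f"{self.name}: negative rate {src}->{dst}")
        if not 0.0 <= self.ccw_bias <= 1.0:
            raise ValueError(f"{self.name}: ccw_bias outside [0, 1]")
        mid, k, pmax = self.wrapped_propensity_params
        if mid <= 0 or k < 0 or not 0.0 <= pmax <= 1.0:
            raise ValueError(f"{self.name}: bad wrapped_propensity_params")
        if self.rot_diffusion < 0 or self.division_rate < 0:
            raise ValueError(f"{self.name}: negative rate")
        for env, p in self.p_motile_daughter.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}: p_motile_daughter[{env}] outside [0, 1]")
        # a wrapped bundle is the slow run mode whenever the strain moves at all
        if self.mode_speed["push"] > 0 and not (
            self.mode_speed["wrapped"] < self.mode_speed["push"]
        ):
            raise ValueError(f"{self.name}: wrapped speed must be below push speed")

    # ------------------------------------------------------------------ #

    @property
    def is_motile(self) -> bool:
        return any(self.mode_speed[m] > 0 for m in RUN_MODES)

    def speeds_in(self, env: "EnvironmentProfile", alpha: float | None = None) -> dict:
        """Per-mode translation speeds (um/s) in ``env``, stop included at 0."""
        base = self.mode_speed
        if env.kind == "agar" and self.mode_speed_agar is not None:
            base = self.mode_speed_agar
        factor = media.viscosity_speed_factor(env.viscosity, alpha)
        out = {m: float(base[m]) * factor for m in RUN_MODES}
        out["stop"] = 0.0
        return out

    def generator_matrix(self, load: float = 1.0) -> np.ndarray:
        """CTMC generator over ``MODES`` at mechanical load ``load`` (cP).

        The configured rates into the two clockwise modes are pooled and
        re-split by the load-dependent wrapped propensity, so raising the
        load converts pull entries into wrapped entries without changing
        the overall CW:CCW balance.  The direct pull->wrapped rate (the
        wrapping instability of a pulling bundle) is likewise scaled by the
        propensity, so a strain that cannot wrap at low load never does.
        """
        p_w = media.wrapped_propensity(self, load)
        Q = np.zeros((len(MODES), len(MODES)))
        for i, src in enumerate(MODES):
            row = dict(self.switch_rate.get(src, {}))
            if src not in CW_MODES:
                cw_total = row.get("pull", 0.0) + row.get("wrapped", 0.0)
                row["wrapped"] = cw_total * p_w
                row["pull"] = cw_total * (1.0 - p_w)
            elif src == "pull" and "wrapped" in row:
                row["wrapped"] = row["wrapped"] * p_w
            for dst, rate in row.items():
                Q[i, MODES.index(dst)] = rate
            Q[i, i] = -sum(rate for dst, rate in row.items())
        return Q

    def stationary_distribution(self, load: float = 1.0) -> np.ndarray:
        """Stationary occupancy of the mode chain, ordered as ``MODES``."""
        Q = self.generator_matrix(load)
        # solve pi Q = 0, sum pi = 1
        A = np.vstack([Q.T, np.ones(len(MODES))])
        b = np.zeros(len(MODES) + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()

    def free_mode_occupancy(self, env: "EnvironmentProfile", alpha: float | None = None) -> np.ndarray:
        """Stationary occupancy of (mode, free-swimming), ordered as ``MODES``.

        In agar the trap encounter rate scales with the mode speed, so the
        freely swimming subpopulation is enriched in slow modes relative to
        the plain mode chain.  Solved exactly on the joint chain over
        (mode) x (free, trapped): mode switching runs at the configured
        rates in both trap states, trap entry from mode ``m`` fires at
        ``trap_rate_per_um * v_m`` and release at ``1 / trap_duration_mean``.
        In bulk this reduces to the plain stationary distribution.
        """
        Q = self.generator_matrix(env.load)
        n = len(MODES)
        speeds = self.speeds_in(env, alpha)
        v = np.array([speeds[m] for m in MODES])
        lam = env.trap_rate_per_um * v
        if not lam.any():
            return self.stationary_distribution(env.load)
        mu = 1.0 / env.trap_duration_mean
        # joint generator, states [(m, free) x n, (m, trapped) x n]
        Q8 = np.zeros((2 * n, 2 * n))
        Q8[:n, :n] = Q
        Q8[n:, n:] = Q
        for i in range(n):
            Q8[i, n + i] = lam[i]
            Q8[n + i, i] = mu
        np.fill_diagonal(Q8, 0.0)
        np.fill_diagonal(Q8, -Q8.sum(axis=1))
        A = np.vstack([Q8.T, np.ones(2 * n)])
        b = np.zeros(2 * n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi[:n] / pi.sum()

    def run_speed_mean(self, env: "EnvironmentProfile", alpha: float | None = None) -> float:
        """Mixture mean run speed (um/s) in ``env``: occupancy-weighted mean
        over the three run modes among freely swimming cells (stops and
        trapped timepoints excluded)."""
        pi_free = self.free_mode_occupancy(env, alpha)
        speeds = self.speeds_in(env, alpha)
        w = np.array([pi_free[MODES.index(m)] for m in RUN_MODES])
        v = np.array([speeds[m] for m in RUN_MODES])
        if w.sum() == 0:
            return 0.0
        return float((w * v).sum() / w.sum())

    def reorientation_rate(self, env: "EnvironmentProfile") -> float:
        """Mean rate (1/s) at which a running cell loses its heading.

        Occupancy-weighted rate of leaving the current run mode through a
        stop or a reversal, plus (in agar) the trap-encounter rate along the
        run path.  The inverse is the run correlation time used for the
        effective diffusivity.
        """
        Q = self.generator_matrix(env.load)
        pi = self.stationary_distribution(env.load)
        run_idx = [MODES.index(m) for m in RUN_MODES]
        w = pi[run_idx]
        if w.sum() == 0:
            return np.inf
        exit_rates = np.array([-Q[i, i] for i in run_idx])
        rate = float((w * exit_rates).sum() / w.sum())
        if env.kind == "agar":
            rate += self.run_speed_mean(env) * env.trap_rate_per_um
        return rate

    def motile_daughter_prob(self, env: "EnvironmentProfile") -> float:
        """P(daughter is motile after division) in ``env``.

        Looked up by environment name, then by environment kind; defaults
        to 1 (every daughter swims away) when unconfigured.
        """
        if env.name in self.p_motile_daughter:
            return float(self.p_motile_daughter[env.name])
        if env.kind in self.p_motile_daughter:
            return float(self.p_motile_daughter[env.kind])
        return 1.0


@dataclass(frozen=True)
class EnvironmentProfile:
    """One medium: bulk fluid (possibly Ficoll-thickened) or semisolid agar."""

    name: str
    kind: str  # "bulk" | "agar"
    viscosity: float = 1.0  # cP of the fluid phase
    ficoll_pct: float = 0.0  # % wt/vol
    agar_pct: float = 0.0  # %
    pore_range_nm: tuple[float, float] = (0.0, 0.0)
    #: trap encounters per um of run path at the reference pore diameter
    trap_rate: float = 0.0
    #: mean immobilization time per trap, s
    trap_duration_mean: float = 1.0
    #: mechanical load proxy (cP equivalent) felt by the flagellar bundle;
    #: defaults to the fluid viscosity, but the agar meshwork loads the
    #: bundle far beyond its 1-cP fluid phase
    load_cP: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("bulk", "agar"):
            raise ValueError(f"{self.name}: kind must be 'bulk' or 'agar'")
        if self.viscosity < 1.0:
            raise ValueError(f"{self.name}: viscosity below 1 cP")
        lo, hi = self.pore_range_nm
        if lo > hi or lo < 0:
            raise ValueError(f"{self.name}: invalid pore range {self.pore_range_nm}")
        if self.kind == "bulk" and self.trap_rate != 0.0:
            raise ValueError(f"{self.name}: bulk environments cannot trap")
        if self.kind == "agar" and hi <= 0:
            raise ValueError(f"{self.name}: agar environment needs a pore range")
        if self.trap_rate < 0 or self.trap_duration_mean < 0:
            raise ValueError(f"{self.name}: negative trap parameter")

    @property
    def load(self) -> float:
        return float(self.viscosity if self.load_cP is None else self.load_cP)

    @property
    def mean_pore_nm(self) -> float:
        return 0.5 * (self.pore_range_nm[0] + self.pore_range_nm[1])

    @property
    def trap_rate_per_um(self) -> float:
        """Effective trap encounters per um of run path (1/pore scaling)."""
        if self.kind == "bulk" or self.trap_rate == 0.0:
            return 0.0
        return float(self.trap_rate * REFERENCE_PORE_NM / self.mean_pore_nm)

    def sample_pore_nm(self, rng: np.random.Generator, size: int | None = None):
        """Draw pore diameters (nm) uniformly from the configured range."""
        if self.kind != "agar":
            raise ValueError(f"{self.name}: pore sampling only defined for agar")
        lo, hi = self.pore_range_nm
        return rng.uniform(lo, hi, size=size)


# ---------------------------------------------------------------------- #
# YAML loading


def _strain_from_dict(name: str, d: Mapping) -> StrainProfile:
    return StrainProfile(
        name=name,
        mode_speed={k: float(v) for k, v in d["mode_speed"].items()},
        switch_rate={
            src: {dst: float(r) for dst, r in row.items()}
            for src, row in d["switch_rate"].items()
        },
        ccw_bias=float(d.get("ccw_bias", 0.5)),
        wrapped_propensity_params=tuple(float(x) for x in d["wrapped_propensity_params"]),
        propensity_shape=d.get("propensity_shape", "logistic"),
        rot_diffusion=float(d.get("rot_diffusion", 0.1)),
        division_rate=float(d.get("division_rate", 0.9)),
        p_motile_daughter={k: float(v) for k, v in d.get("p_motile_daughter", {}).items()},
        mode_speed_agar=(
            {k: float(v) for k, v in d["mode_speed_agar"].items()}
            if "mode_speed_agar" in d
            else None
        ),
        reversal_jitter_deg=float(d.get("reversal_jitter_deg", 15.0)),
    )


def _env_from_dict(name: str, d: Mapping) -> EnvironmentProfile:
    return EnvironmentProfile(
        name=name,
        kind=d["kind"],
        viscosity=float(d.get("viscosity", 1.0)),
        ficoll_pct=float(d.get("ficoll_pct", 0.0)),
        agar_pct=float(d.get("agar_pct", 0.0)),
        pore_range_nm=tuple(float(x) for x in d.get("pore_range_nm", (0.0, 0.0))),
        trap_rate=float(d.get("trap_rate", 0.0)),
        trap_duration_mean=float(d.get("trap_duration_mean", 1.0)),
        load_cP=(float(d["load_cP"]) if "load_cP" in d else None),
    )


def load_profiles(path) -> tuple[dict, dict]:
    """Load ``(strains, environments)`` from a YAML profile file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    strains = {n: _strain_from_dict(n, d) for n, d in raw.get("strains", {}).items()}
    envs = {n: _env_from_dict(n, d) for n, d in raw.get("environments", {}).items()}
    return strains, envs


def load_default_profiles() -> tuple[dict, dict]:
    """Load the profiles shipped with the package."""
    ref = resources.files("swimtrack").joinpath("data/profiles.yaml")
    with resources.as_file(ref) as path:
        return load_profiles(path)


def get_strain(name: str) -> StrainProfile:
    strains, _ = load_default_profiles()
    try:
        return strains[name]
    except KeyError:
        raise KeyError(f"unknown strain {name!r}; available: {sorted(strains)}") from None


def get_environment(name: str) -> EnvironmentProfile:
    _, envs = load_default_profiles()
    try:
        return envs[name]
    except KeyError:
        raise KeyError(f"unknown environment {name!r}; available: {sorted(envs)}") from None
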