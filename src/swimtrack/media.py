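"""Fluid-medium physics used by the swimmer generator.

Three small pieces of plumbing live here:

* the Ficoll concentration -> viscosity lookup for the standard
  Ficoll 400 dilutions (10 / 15 / 20 % wt/vol correspond to 5 / 10 / 18 cP,
  with plain aqueous medium at 1 cP),
* a power-law viscous-slowdown factor ``v(eta) = v0 * eta**(-alpha)`` whose
  default exponent is calibrated once against the wild-type mean-speed vs
  viscosity reference points, and
* the load-dependent propensity of a clockwise-rotating flagellar bundle to
  wrap around the cell body instead of pulling it.
"""

from __future__ import annotations

import functools

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.special import expit

__all__ = [
    "FICOLL_PCT_ANCHORS",
    "FICOLL_CP_ANCHORS",
    "WT_SPEED_VS_VISCOSITY",
    "ficoll_viscosity",
    "fit_speed_exponent",
    "default_speed_exponent",
    "viscosity_speed_factor",
    "wrapped_propensity",
]

#: Ficoll 400 concentration anchors (% wt/vol) and the matching dynamic
#: viscosities (cP).  0 % is the aqueous baseline.
FICOLL_PCT_ANCHORS: tuple[float, ...] = (0.0, 10.0, 15.0, 20.0)
FICOLL_CP_ANCHORS: tuple[float, ...] = (1.0, 5.0, 10.0, 18.0)

#: Wild-type whole-trajectory mean speeds (viscosity cP, speed um/s) used to
#: calibrate the default viscous-slowdown exponent.
WT_SPEED_VS_VISCOSITY: tuple[tuple[float, float], ...] = (
    (1.0, 32.1),
    (5.0, 11.4),
    (10.0, 8.9),
    (18.0, 6.3),
)


@functools.lru_cache(maxsize=1)
def _ficoll_interpolator() -> PchipInterpolator:
    # monotone (PCHIP) interpolation on log-viscosity: passes exactly through
    # the anchors and cannot overshoot between them
    return PchipInterpolator(FICOLL_PCT_ANCHORS, np.log(FICOLL_CP_ANCHORS))


def ficoll_viscosity(pct: float) -> float:
    """Viscosity (cP) of medium with ``pct`` % wt/vol Ficoll 400.

    Exact at the calibration anchors 0/10/15/20 % (1/5/10/18 cP); between
    anchors a monotone interpolation on log-viscosity is used.  Values
    outside [0, 20] % are refused: there is no calibration beyond 20 %.
    """
    pct = float(pct)
    if not 0.0 <= pct <= FICOLL_PCT_ANCHORS[-1]:
        raise ValueError(
            f"Ficoll concentration {pct}% outside the calibrated range "
            f"[0, {FICOLL_PCT_ANCHORS[-1]}] % wt/vol"
        )
    return float(np.exp(_ficoll_interpolator()(pct)))


def fit_speed_exponent(points) -> float:
    """Least-squares exponent ``alpha`` of ``v = v0 * eta**(-alpha)``.

    ``points`` is an iterable of ``(viscosity_cP, speed_um_s)`` pairs; the fit
    is ordinary least squares of log-speed on log-viscosity.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (viscosity, speed) points")
    if np.any(pts <= 0):
        raise ValueError("viscosities and speeds must be positive")
    slope = np.polyfit(np.log(pts[:, 0]), np.log(pts[:, 1]), 1)[0]
    return float(-slope)


@functools.lru_cache(maxsize=1)
def default_speed_exponent() -> float:
    """Default slowdown exponent, fitted to the wild-type reference points."""
    return fit_speed_exponent(WT_SPEED_VS_VISCOSITY)


def viscosity_speed_factor(viscosity: float, alpha: float | None = None) -> float:
    """Dimensionless speed scale ``(viscosity / 1 cP) ** (-alpha)`` in (0, 1].

    ``alpha`` defaults to the calibrated exponent from
    :func:`default_speed_exponent`.  Viscosities below the aqueous baseline
    of 1 cP are outside the model's domain.
    """
    viscosity = float(viscosity)
    if viscosity < 1.0:
        raise ValueError(f"viscosity {viscosity} cP below aqueous baseline (1 cP)")
    if alpha is None:
        alpha = default_speed_exponent()
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    return float(viscosity ** (-alpha))


def wrapped_propensity(strain, load: float) -> float:
    """P(wrapped | clockwise bundle rotation) at mechanical load ``load`` (cP equivalent).

    Two shapes are supported, selected by ``strain.propensity_shape``:

    ``"logistic"``
        ``p = pmax * sigmoid(k * (ln load - ln midpoint))`` -- monotone rise
        that saturates near ``pmax``; used for strains whose wrapped-mode
        share keeps increasing with load.
    ``"peaked"``
        a log-normal-shaped bump centred at ``midpoint`` with log-width ``k``,
        baseline-subtracted so the propensity is exactly 0 at load 1 (bulk):
        strains that only wrap at intermediate load and lose the mode again
        at the highest loads.

    ``strain.wrapped_propensity_params`` is ``(midpoint, k, pmax)``.
    """
    load = float(load)
    if load < 1.0:
        raise ValueError(f"load {load} below the aqueous baseline of 1 cP")
    midpoint, k, pmax = strain.wrapped_propensity_params
    shape = getattr(strain, "propensity_shape", "logistic")
    if pmax == 0.0:
        return 0.0
    x = np.log(load)
    mu = np.log(midpoint)
    if shape == "logistic":
        p = pmax * expit(k * (x - mu))
    elif shape == "peaked":
        f = np.exp(-((x - mu) ** 2) / (2.0 * k**2))
        f0 = np.exp(-(mu**2) / (2.0 * k**2))  # value at load 1
        p = pmax * max(0.0, (f - f0) / (1.0 - f0))
    else:
        raise ValueError(f"unknown propensity shape {shape!r}")
    return float(min(max(p, 0.0), pmax))
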