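"""Swimming-mode tabulation and spreading-front fits.

Run modes are counted into push / pull / wrapped fractions with exact
(Clopper–Pearson) binomial confidence intervals; pull and wrapped together
form the clockwise (CW) fraction.  Colony-spreading series are fitted with
a flat lag followed by a straight front, and strain fits are compared by
slope ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import SpreadingSeries

__all__ = [
    "ModeTable",
    "SpreadingFit",
    "tabulate_modes",
    "cw_mode_split",
    "fit_spreading",
    "compare_strains",
]

MODE_LABELS = ("push", "pull", "wrapped")
CW_LABELS = ("pull", "wrapped")


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval for ``k`` successes in ``n``."""
    if not 0 <= k <= n or n == 0:
        raise ValueError("need 0 <= k <= n with n > 0")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass
class ModeTable:
    counts: dict  # mode -> count
    fractions: dict  # mode -> fraction
    ci: dict  # mode -> (lo, hi), exact binomial
    cw_fraction: float  # pull + wrapped
    n: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "mode": m,
                    "count": self.counts[m],
                    "fraction": self.fractions[m],
                    "ci_lo": self.ci[m][0],
                    "ci_hi": self.ci[m][1],
                }
                for m in MODE_LABELS
            ]
        )


def tabulate_modes(run_labels, alpha: float = 0.05) -> ModeTable:
    """Count run-mode labels into a :class:`ModeTable`.

    ``run_labels`` is an iterable of ``push`` / ``pull`` / ``wrapped``
    (one per observed run).  Raises on an empty list or unknown labels.
    """
    labels = list(run_labels)
    if not labels:
        raise ValueError("no run labels to tabulate")
    bad = set(labels) - set(MODE_LABELS)
    if bad:
        raise ValueError(f"unknown mode labels: {sorted(bad)}")
    n = len(labels)
    counts = {m: labels.count(m) for m in MODE_LABELS}
    fractions = {m: counts[m] / n for m in MODE_LABELS}
    ci = {m: clopper_pearson(counts[m], n, alpha) for m in MODE_LABELS}
    cw = sum(fractions[m] for m in CW_LABELS)
    return ModeTable(counts=counts, fractions=fractions, ci=ci, cw_fraction=cw, n=n)


def cw_mode_split(table: ModeTable) -> tuple[float, float]:
    """(pull, wrapped) fractions conditional on clockwise rotation."""
    cw_count = sum(table.counts[m] for m in CW_LABELS)
    if cw_count == 0:
        raise ValueError("no clockwise runs: pull/wrapped split undefined")
    return (table.counts["pull"] / cw_count, table.counts["wrapped"] / cw_count)


# ---------------------------------------------------------------------- #
# spreading fronts


@dataclass
class SpreadingFit:
    slope: float  # mm/h, linear-regime slope of the diameter
    intercept: float  # mm, at t = 0 of the fitted line
    lag_h: float  # detected flat lag before the front moves
    residual_rms: float  # mm, over the fitted window
    window: tuple[float, float]  # (t_start, t_end) of the linear regime, h


def _prefix_flat(t: np.ndarray, d: np.ndarray, alpha: float = 0.05) -> int:
    """Index of the first point where an expanding initial window stops
    being statistically consistent with zero slope (slope t-test)."""
    n = len(t)
    for k in range(3, n + 1):
        res = stats.linregress(t[:k], d[:k])
        if res.stderr == 0.0 or np.isnan(res.stderr):
            significant = res.slope != 0.0
        else:
            significant = res.pvalue < alpha
        if significant:
            # no flat prefix at all if even the smallest window has a slope
            return 0 if k == 3 else k - 1
    return n - 1


def fit_spreading(series: SpreadingSeries, alpha: float = 0.05) -> SpreadingFit:
    """Fit lag + linear front to a colony-diameter series.

    The lag is first detected as the longest initial window statistically
    consistent with zero slope; a least-squares line is fitted beyond it.
    The lag is then refined once from the intersection of that line with
    the initial diameter level and the line refitted, which recovers the
    slope of a noiseless lag-plus-line series exactly.  A series that
    shrinks beyond noise draws a warning, not an error.
    """
    t = np.asarray(series.times_h, dtype=float)
    d = np.asarray(series.diameter_mm, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least three timepoints")
    if np.any(np.diff(d) < -1e-6 * max(1.0, np.abs(d).max())):
        warnings.warn("colony diameter decreases beyond noise")

    if np.allclose(d, d[0]):
        return SpreadingFit(slope=0.0, intercept=float(d[0]), lag_h=float(t[-1]),
                            residual_rms=0.0, window=(float(t[0]), float(t[-1])))

    b = _prefix_flat(t, d, alpha)
    b = min(b, len(t) - 2)  # keep at least two points for the fit

    def line_fit(start: int):
        slope, intercept = np.polyfit(t[start:], d[start:], 1)
        resid = d[start:] - (slope * t[start:] + intercept)
        return float(slope), float(intercept), float(np.sqrt(np.mean(resid**2))), start

    slope, intercept, rms, start = line_fit(b)
    # refine: the front leaves the baseline where the fitted line crosses it
    if slope > 0:
        baseline = float(np.median(d[: max(b, 1)])) if b >= 1 else float(d[0])
        t_cross = (baseline - intercept) / slope
        start2 = int(np.searchsorted(t, t_cross - 1e-9))
        start2 = min(max(start2, 0), len(t) - 2)
        slope, intercept, rms, start = line_fit(start2)
    lag = float(t[start]) if start > 0 else 0.0
    return SpreadingFit(slope=slope, intercept=intercept, lag_h=lag,
                        residual_rms=rms, window=(float(t[start]), float(t[-1])))


def compare_strains(fits: dict) -> pd.DataFrame:
    """Rank strains by spreading slope and report pairwise slope ratios.

    ``fits`` maps strain name -> :class:`SpreadingFit`.  Returns a DataFrame
    ordered fastest-first with columns ``strain, slope_mm_h, rank,
    ratio_to_fastest`` plus one ``ratio_vs_<strain>`` column per strain.
    """
    if len(fits) < 2:
        raise ValueError("need at least two strains to compare")
    names = list(fits)
    slopes = {s: fits[s].slope for s in names}
    order = sorted(names, key=lambda s: -slopes[s])
    top = slopes[order[0]]
    rows = []
    for rank, s in enumerate(order, start=1):
        row = {
            "strain": s,
            "slope_mm_h": slopes[s],
            "rank": rank,
            "ratio_to_fastest": slopes[s] / top if top > 0 else np.nan,
        }
        for other in names:
            denom = slopes[other]
            row[f"ratio_vs_{other}"] = slopes[s] / denom if denom > 0 else np.inf if slopes[s] > 0 else 1.0
        rows.append(row)
    return pd.DataFrame(rows)
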