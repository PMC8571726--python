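"""Population tuning-curve characterization.

Numerosity tuning in cortex-like systems follows the Weber–Fechner law:
tuning curves are asymmetric on a linear number axis but become symmetric —
and are better fit by Gaussians — when numerosity is plotted on a
logarithmic axis, and tuning width grows with preferred numerosity (the
numerical size effect).  This module quantifies those signatures for a
population of units:

* population tuning curves (mean ± s.e. of normalized curves per preferred
  numerosity),
* least-squares Gaussian and straight-line fits of tuning curves on linear
  and logarithmic numerosity axes, compared by paired Wilcoxon signed-rank
  tests on r²,
* the numerical distance effect for zero-preferring units (response to 1
  vs 2 and 2 vs 3) and the size effect (Pearson correlation of preferred
  numerosity with fitted Gaussian width).

Because numerosity 0 must sit at a finite position on the logarithmic axis,
the log transform is x' = log2(x + 1) (configurable), which maps 0 -> 0 and
compresses spacing with magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from .selectivity import TuningProfile

__all__ = [
    "GaussianFit",
    "LineFit",
    "ScaleComparison",
    "EffectStats",
    "PopulationCurve",
    "log_axis",
    "population_curves",
    "fit_gaussian",
    "fit_line",
    "fits_table",
    "distance_size_effects",
    "scale_comparison",
]

MIN_PAIRS = 5  # minimum paired samples for a Wilcoxon comparison


def log_axis(x: np.ndarray) -> np.ndarray:
    """Logarithmic numerosity axis keeping 0 finite: log2(x + 1)."""
    return np.log2(np.asarray(x, dtype=float) + 1.0)


def _axis_values(x: np.ndarray, axis: str) -> np.ndarray:
    if axis == "linear":
        return np.asarray(x, dtype=float)
    if axis == "log":
        return log_axis(x)
    raise ValueError("axis must be 'linear' or 'log'")


# ---------------------------------------------------------------------------
# Population curves
# ---------------------------------------------------------------------------


@dataclass
class PopulationCurve:
    preferred_numerosity: int
    numerosities: np.ndarray
    mean: np.ndarray  # across-unit mean of normalized curves
    sem: np.ndarray  # across-unit standard error
    n_units: int


def population_curves(
    profiles: Sequence[TuningProfile],
    normalize_first: bool = True,
) -> list[PopulationCurve]:
    """Average tuning curves of units sharing a preferred numerosity.

    ``normalize_first`` follows the convention of normalizing each unit's
    curve to [0, 1] before averaging; the alternative (average raw curves,
    then min-max normalize the group mean) is available for comparison.
    """
    if not profiles:
        raise ValueError("need at least one tuning profile")
    by_pref: dict[int, list[TuningProfile]] = {}
    for p in profiles:
        by_pref.setdefault(p.preferred_numerosity, []).append(p)
    curves = []
    for pref in sorted(by_pref):
        group = by_pref[pref]
        if normalize_first:
            arr = np.stack([p.normalized_curve for p in group])
        else:
            arr = np.stack([p.pooled_mean for p in group])
        mean = arr.mean(axis=0)
        sem = (
            arr.std(axis=0, ddof=1) / np.sqrt(len(group))
            if len(group) > 1
            else np.zeros_like(mean)
        )
        if not normalize_first:
            lo, hi = mean.min(), mean.max()
            if hi > lo:
                sem = sem / (hi - lo)
                mean = (mean - lo) / (hi - lo)
        curves.append(
            PopulationCurve(
                preferred_numerosity=int(pref),
                numerosities=group[0].numerosities.copy(),
                mean=mean,
                sem=sem,
                n_units=len(group),
            )
        )
    return curves


# ---------------------------------------------------------------------------
# Curve fitting
# ---------------------------------------------------------------------------


@dataclass
class GaussianFit:
    center: float  # on the fitted (possibly log-transformed) axis
    width_sd: float
    amplitude: float
    baseline: float
    r_squared: float
    axis: str = "linear"
    converged: bool = True


@dataclass
class LineFit:
    slope: float
    intercept: float
    r_squared: float
    axis: str = "linear"


def _gauss(x, amp, center, sd, base):
    return base + amp * np.exp(-0.5 * ((x - center) / sd) ** 2)


def _r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def fit_gaussian(
    curve: np.ndarray,
    numerosities: np.ndarray | None = None,
    axis: str = "linear",
) -> GaussianFit:
    """Least-squares Gaussian fit of a tuning curve on the chosen axis.

    Initialization is deterministic (amplitude = range, center = argmax,
    width = half the axis span, baseline = minimum), so repeated fits are
    bit-identical.  A failed fit is flagged with r² = -inf and excluded
    from paired comparisons downstream.
    """
    y = np.asarray(curve, dtype=float)
    if y.size < 4:
        raise ValueError("need at least 4 curve points for a Gaussian fit")
    if numerosities is None:
        numerosities = np.arange(y.size)
    x = _axis_values(numerosities, axis)
    span = x.max() - x.min()
    p0 = [y.max() - y.min() or 1.0, x[int(np.argmax(y))], span / 2, y.min()]
    # keep center within one span of the sampled range and width below a
    # few spans: monotone curves otherwise drive the optimizer down an
    # unbounded center/width ridge
    min_sd = 0.05 * span
    lo = [-np.inf, x.min() - span, min_sd, -np.inf]
    hi = [np.inf, x.max() + span, 10 * span, np.inf]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                _gauss, x, y, p0=p0, bounds=(lo, hi), maxfev=10_000
            )
        amp, center, sd, base = popt
        return GaussianFit(
            center=float(center),
            width_sd=float(sd),
            amplitude=float(amp),
            baseline=float(base),
            r_squared=_r2(y, _gauss(x, *popt)),
            axis=axis,
        )
    except (RuntimeError, optimize.OptimizeWarning):
        return GaussianFit(
            center=float("nan"),
            width_sd=float("nan"),
            amplitude=float("nan"),
            baseline=float("nan"),
            r_squared=-np.inf,
            axis=axis,
            converged=False,
        )


def fit_line(
    curve: np.ndarray,
    numerosities: np.ndarray | None = None,
    axis: str = "linear",
) -> LineFit:
    """Ordinary least-squares straight-line fit on the chosen axis."""
    y = np.asarray(curve, dtype=float)
    if numerosities is None:
        numerosities = np.arange(y.size)
    x = _axis_values(numerosities, axis)
    slope, intercept = np.polyfit(x, y, 1)
    return LineFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=_r2(y, slope * x + intercept),
        axis=axis,
    )


# ---------------------------------------------------------------------------
# Effect statistics
# ---------------------------------------------------------------------------


def fits_table(profiles: Sequence[TuningProfile], axes=("linear", "log")):
    """Per-unit Gaussian fit results (one row per unit and axis)."""
    import pandas as pd

    rows = []
    for p in profiles:
        for axis in axes:
            f = fit_gaussian(p.normalized_curve, p.numerosities, axis=axis)
            rows.append(
                {
                    "unit_id": p.unit_id,
                    "preferred_numerosity": p.preferred_numerosity,
                    "axis": axis,
                    "center": f.center,
                    "width_sd": f.width_sd,
                    "r_squared": f.r_squared,
                    "converged": f.converged,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class EffectStats:
    """Distance-effect comparisons for zero-preferring units and the
    size-effect correlation across all units."""

    n_zero_units: int
    wilcoxon_1v2_stat: float
    wilcoxon_1v2_p: float
    wilcoxon_2v3_stat: float
    wilcoxon_2v3_p: float
    size_effect_r: float
    size_effect_p: float
    skipped: bool = False


def _wilcoxon(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank; exact for n <= 25.

    Identical paired samples carry no evidence either way -> p = 1.
    """
    d = np.asarray(a, float) - np.asarray(b, float)
    if np.all(d == 0):
        return 0.0, 1.0
    method = "exact" if len(d) <= 25 else "approx"
    res = stats.wilcoxon(a, b, method=method, zero_method="wilcox")
    return float(res.statistic), float(res.pvalue)


def distance_size_effects(
    profiles: Sequence[TuningProfile],
    gaussian_axis: str = "log",
) -> EffectStats:
    """Numerical distance and size effects over a unit population.

    Distance effect: paired Wilcoxon signed-rank across zero-preferring
    units of the normalized response to numerosity 1 vs 2 and 2 vs 3.
    Size effect: Pearson correlation between each unit's preferred
    numerosity and the width of the Gaussian fit to its tuning curve.
    """
    zero = [p for p in profiles if p.preferred_numerosity == 0]
    s1 = p1 = s2 = p2 = float("nan")
    if len(zero) < MIN_PAIRS:
        warnings.warn(
            f"only {len(zero)} zero-preferring units (< {MIN_PAIRS}); "
            "distance-effect tests skipped"
        )
        skipped = True
    else:
        nums = list(zero[0].numerosities)
        r = np.stack([p.normalized_curve for p in zero])
        if 1 in nums and 2 in nums:
            s1, p1 = _wilcoxon(r[:, nums.index(1)], r[:, nums.index(2)])
        if 2 in nums and 3 in nums:
            s2, p2 = _wilcoxon(r[:, nums.index(2)], r[:, nums.index(3)])
        skipped = False
    prefs, widths = [], []
    for p in profiles:
        if p.normalized_curve.size < 4:
            continue
        fit = fit_gaussian(p.normalized_curve, p.numerosities, axis=gaussian_axis)
        if fit.converged and np.isfinite(fit.width_sd):
            prefs.append(p.preferred_numerosity)
            widths.append(fit.width_sd)
    if len(prefs) >= 3 and len(set(prefs)) > 1:
        r_sz, p_sz = stats.pearsonr(prefs, widths)
    else:
        r_sz, p_sz = float("nan"), float("nan")
    return EffectStats(
        n_zero_units=len(zero),
        wilcoxon_1v2_stat=s1,
        wilcoxon_1v2_p=p1,
        wilcoxon_2v3_stat=s2,
        wilcoxon_2v3_p=p2,
        size_effect_r=float(r_sz),
        size_effect_p=float(p_sz),
        skipped=skipped,
    )


@dataclass
class ScaleComparison:
    """Paired linear-axis vs log-axis goodness of fit over a population."""

    r2_linear: np.ndarray
    r2_log: np.ndarray
    mean_r2_linear: float
    mean_r2_log: float
    wilcoxon_stat: float
    wilcoxon_p: float
    n: int


def scale_comparison(
    profiles: Sequence[TuningProfile] | None = None,
    curves: Sequence[np.ndarray] | None = None,
    numerosities: np.ndarray | None = None,
    fitter: Callable = fit_gaussian,
) -> ScaleComparison:
    """Fit each curve on the linear and the logarithmic numerosity axis and
    compare the paired r² values with a Wilcoxon signed-rank test.

    Accepts either tuning profiles or raw curves; non-convergent fits are
    dropped pairwise.  Refuses fewer than five pairs.
    """
    if (profiles is None) == (curves is None):
        raise ValueError("pass exactly one of profiles or curves")
    if profiles is not None:
        curves = [p.normalized_curve for p in profiles]
        numerosities = profiles[0].numerosities
    r2_lin, r2_log = [], []
    for c in curves:
        flin = fitter(c, numerosities, axis="linear")
        flog = fitter(c, numerosities, axis="log")
        r2a = flin.r_squared
        r2b = flog.r_squared
        if np.isfinite(r2a) and np.isfinite(r2b):
            r2_lin.append(r2a)
            r2_log.append(r2b)
    if len(r2_lin) < MIN_PAIRS:
        raise ValueError(
            f"need at least {MIN_PAIRS} successfully fitted curve pairs, "
            f"got {len(r2_lin)}"
        )
    a, b = np.asarray(r2_lin), np.asarray(r2_log)
    s, p = _wilcoxon(a, b)
    return ScaleComparison(
        r2_linear=a,
        r2_log=b,
        mean_r2_linear=float(a.mean()),
        mean_r2_log=float(b.mean()),
        wilcoxon_stat=s,
        wilcoxon_p=p,
        n=len(a),
    )
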