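"""Numerosity-selectivity screening and per-unit tuning profiles.

A unit is *numerosity selective* when a two-factor fixed-effects ANOVA on
its responses — factors numerosity (5 levels for the 0–4 study) and stimulus
set (3 levels) — shows a significant main effect of numerosity (p < 0.01)
and no significant effect of stimulus set or of the interaction (both
p >= 0.01).  This is the same screen used on single neurons in the
electrophysiology literature.  The ANOVA runs vectorized over all units of
an activation matrix; the design is balanced by construction (the stimulus
generator emits equal cell counts), under which the classical Type I/II/III
decompositions coincide.

A unit's tuning curve is its mean response per numerosity; the preferred
numerosity is the curve's peak (ties broken toward the smaller numerosity),
and curves are min-max normalized to [0, 1] for population analyses.
Constant-response (dead-ReLU) units have an undefined F statistic; they are
excluded from the ANOVA but kept in the unit-count denominator.

``untrained_repetition_study`` runs the whole protocol — fresh random
weights, fresh stimuli, noisy presentation, screen, profiles — over several
repetitions and aggregates the summary statistics across them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hcnn import (
    ActivationMatrix,
    NetworkConfig,
    NoiseParams,
    build_network,
    calibrate_batch_norm,
    default_config,
    forward_record,
)
from .stimuli import SETS, StimulusManifest, generate_manifest

__all__ = [
    "AnovaResult",
    "TuningProfile",
    "SelectivityScreenSummary",
    "two_way_anova",
    "screen_selectivity",
    "tuning_profiles",
    "response_variability",
    "group_curve_spread",
    "untrained_repetition_study",
    "profiles_table",
]


@dataclass
class AnovaResult:
    unit_id: int
    p_numerosity: float
    p_set: float
    p_interaction: float
    excluded_constant: bool = False


@dataclass
class TuningProfile:
    unit_id: int
    numerosities: np.ndarray  # the tested numerosity levels
    mean_response: np.ndarray  # (n_numerosity, n_sets) per-set means
    pooled_mean: np.ndarray  # (n_numerosity,)
    preferred_numerosity: int
    normalized_curve: np.ndarray  # pooled curve min-max scaled to [0, 1]
    sets: tuple = ()


@dataclass
class SelectivityScreenSummary:
    """Across-repetition aggregate of the selectivity screen."""

    n_units_total: int
    n_reps: int
    fraction_selective: float
    fraction_selective_se: float
    fraction_zero_preferring: float
    fraction_zero_preferring_se: float
    preferred_histogram: np.ndarray  # mean count per numerosity, over reps
    numerosities: tuple
    response_variability: float  # mean s.d. of normalized responses
    response_variability_se: float
    per_rep: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# Two-way ANOVA (balanced, vectorized over units)
# ---------------------------------------------------------------------------


def two_way_anova(
    X: np.ndarray, fa: np.ndarray, fb: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Classical balanced two-way fixed-effects ANOVA with interaction,
    vectorized over rows of ``X``.

    X: (n_units, n_obs); fa, fb: integer factor labels per observation.
    Returns (p_a, p_b, p_ab); rows with zero total variance get NaN.
    """
    X = np.asarray(X, dtype=np.float64)
    fa = np.asarray(fa)
    fb = np.asarray(fb)
    a_levels, fa_i = np.unique(fa, return_inverse=True)
    b_levels, fb_i = np.unique(fb, return_inverse=True)
    a, b = len(a_levels), len(b_levels)
    cell = fa_i * b + fb_i
    counts = np.bincount(cell, minlength=a * b)
    if counts.min() != counts.max():
        raise ValueError("unbalanced design: unequal cell counts")
    r = int(counts[0])
    if r < 2:
        raise ValueError("need at least 2 observations per cell")
    n = X.shape[1]

    # cell sums via one matmul: (units, obs) @ (obs, a*b)
    M = np.zeros((n, a * b))
    M[np.arange(n), cell] = 1.0
    cell_mean = (X @ M) / r  # (units, a*b)
    cm = cell_mean.reshape(-1, a, b)
    mean_a = cm.mean(axis=2)  # (units, a)
    mean_b = cm.mean(axis=1)  # (units, b)
    grand = cm.mean(axis=(1, 2))

    ss_a = r * b * np.sum((mean_a - grand[:, None]) ** 2, axis=1)
    ss_b = r * a * np.sum((mean_b - grand[:, None]) ** 2, axis=1)
    inter = cm - mean_a[:, :, None] - mean_b[:, None, :] + grand[:, None, None]
    ss_ab = r * np.sum(inter**2, axis=(1, 2))
    ss_tot = np.sum((X - X.mean(axis=1, keepdims=True)) ** 2, axis=1)
    ss_err = np.maximum(ss_tot - ss_a - ss_b - ss_ab, 0.0)

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_err = a * b * (r - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mse = ss_err / df_err
        f_a = (ss_a / df_a) / mse
        f_b = (ss_b / df_b) / mse
        f_ab = (ss_ab / df_ab) / mse
    p_a = stats.f.sf(f_a, df_a, df_err)
    p_b = stats.f.sf(f_b, df_b, df_err)
    p_ab = stats.f.sf(f_ab, df_ab, df_err)
    constant = ss_tot <= 0
    for p in (p_a, p_b, p_ab):
        p[constant] = np.nan
    return p_a, p_b, p_ab


def screen_selectivity(
    acts: ActivationMatrix,
    manifest: StimulusManifest,
    alpha: float = 0.01,
) -> tuple[list[AnovaResult], np.ndarray]:
    """Run the two-factor screen on every unit.

    Returns the per-unit ANOVA results and the array of selective unit ids
    (significant numerosity effect, no set or interaction effect).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    table = manifest.table
    fa = table["numerosity"].to_numpy()
    fb = pd.Categorical(table["set"]).codes
    p_num, p_set, p_int = two_way_anova(acts.values, fa, fb)
    constant = np.isnan(p_num)
    selective = (~constant) & (p_num < alpha) & (p_set >= alpha) & (p_int >= alpha)
    results = [
        AnovaResult(
            unit_id=i,
            p_numerosity=float(p_num[i]),
            p_set=float(p_set[i]),
            p_interaction=float(p_int[i]),
            excluded_constant=bool(constant[i]),
        )
        for i in range(acts.n_units)
    ]
    return results, np.flatnonzero(selective)


# ---------------------------------------------------------------------------
# Tuning profiles
# ---------------------------------------------------------------------------


def tuning_profiles(
    acts: ActivationMatrix,
    manifest: StimulusManifest,
    unit_ids: Sequence[int],
    warn_flat: bool = True,
) -> list[TuningProfile]:
    """Per-set and pooled mean tuning curves for the given units.

    Preferred numerosity is the pooled-curve argmax (ties -> smaller
    numerosity); flat pooled curves are dropped with a warning.
    """
    unit_ids = np.asarray(unit_ids)
    if unit_ids.size == 0:
        raise ValueError("unit subset is empty")
    table = manifest.table
    nums = np.array(sorted(table["numerosity"].unique()))
    sets = tuple(sorted(table["set"].unique()))
    profiles = []
    flat_dropped = 0
    X = acts.values[unit_ids]
    set_codes = pd.Categorical(table["set"], categories=sets).codes
    num_idx = np.searchsorted(nums, table["numerosity"].to_numpy())
    per_set = np.zeros((len(unit_ids), len(nums), len(sets)))
    pooled = np.zeros((len(unit_ids), len(nums)))
    for qi in range(len(nums)):
        sel_q = num_idx == qi
        pooled[:, qi] = X[:, sel_q].mean(axis=1)
        for si in range(len(sets)):
            sel = sel_q & (set_codes == si)
            per_set[:, qi, si] = X[:, sel].mean(axis=1)
    for k, uid in enumerate(unit_ids):
        pm = pooled[k]
        lo, hi = pm.min(), pm.max()
        if hi - lo <= 0:
            flat_dropped += 1
            continue
        pref = int(nums[int(np.argmax(pm))])  # argmax returns the first max
        profiles.append(
            TuningProfile(
                unit_id=int(uid),
                numerosities=nums.copy(),
                mean_response=per_set[k],
                pooled_mean=pm,
                preferred_numerosity=pref,
                normalized_curve=(pm - lo) / (hi - lo),
                sets=sets,
            )
        )
    if flat_dropped and warn_flat:
        import warnings

        warnings.warn(f"dropped {flat_dropped} units with flat tuning curves")
    return profiles


def profiles_table(profiles: list[TuningProfile]) -> pd.DataFrame:
    """Per-unit results table (one row per unit, per-numerosity means as
    columns)."""
    rows = []
    for p in profiles:
        row = {"unit_id": p.unit_id, "preferred_numerosity": p.preferred_numerosity}
        for q, m in zip(p.numerosities, p.pooled_mean):
            row[f"mean_n{q}"] = m
        rows.append(row)
    return pd.DataFrame(rows)


def response_variability(
    acts: ActivationMatrix,
    manifest: StimulusManifest,
    profiles: list[TuningProfile],
) -> float:
    """Average standard error of the normalized responses.

    Each unit's single-presentation responses are min-max normalized with
    its pooled tuning-curve range; for every (numerosity, stimulus set) cell
    the standard error over that cell's presentations is taken, and the
    values are averaged over cells and units.  Large values mean
    presentation-to-presentation variability is large relative to the depth
    of the tuning curve.
    """
    if not profiles:
        return float("nan")
    table = manifest.table
    fa = table["numerosity"].to_numpy()
    fb = pd.Categorical(table["set"]).codes
    cells = [(q, s) for q in np.unique(fa) for s in np.unique(fb)]
    unit_ids = np.array([p.unit_id for p in profiles])
    X = acts.values[unit_ids].astype(np.float64)
    lo = np.array([p.pooled_mean.min() for p in profiles])
    rng_ = np.array([p.pooled_mean.max() - p.pooled_mean.min() for p in profiles])
    Z = (X - lo[:, None]) / rng_[:, None]
    sems = []
    for q, s in cells:
        sel = (fa == q) & (fb == s)
        n = int(sel.sum())
        if n < 2:
            continue
        sems.append(Z[:, sel].std(axis=1, ddof=1) / np.sqrt(n))
    return float(np.mean(np.concatenate(sems))) if sems else float("nan")


def group_curve_spread(profiles: list[TuningProfile]) -> float:
    """Across-unit standard deviation of normalized tuning curves within
    preferred-numerosity groups, averaged over numerosities and groups — a
    measure of how heterogeneous the tuning shapes are inside each group."""
    by_pref: dict[int, list[np.ndarray]] = {}
    for p in profiles:
        by_pref.setdefault(p.preferred_numerosity, []).append(p.normalized_curve)
    vals = []
    for curves in by_pref.values():
        if len(curves) < 2:
            continue
        arr = np.stack(curves)
        vals.extend(arr.std(axis=0, ddof=1))
    return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# Untrained-network repetition study
# ---------------------------------------------------------------------------


def untrained_repetition_study(
    config: NetworkConfig | None = None,
    n_reps: int = 5,
    base_seed: int = 0,
    numerosities: Sequence[int] = (0, 1, 2, 3, 4),
    sets: Sequence[str] = SETS,
    n_images: int = 600,
    alpha: float = 0.01,
    noise: NoiseParams | None = None,
    layer_index: int | None = None,
    calibrate: bool = False,
    calib_per_cell: int = 6,
) -> SelectivityScreenSummary:
    """Repeated screen of untrained networks: per repetition, draw fresh
    Xavier weights, generate a fresh balanced stimulus batch, record the
    final-layer responses with multiplicative noise, screen for selectivity
    and profile the selective units.  Aggregates mean and standard error of
    the headline fractions across repetitions.

    By default the untrained network runs in evaluation mode (batch norm is
    the identity); set ``calibrate=True`` to first standardize each feature
    map on a balanced sample of the stimulus batch."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    config = config or default_config()
    noise = noise if noise is not None else NoiseParams()
    numerosities = tuple(numerosities)
    ss = np.random.SeedSequence(base_seed)
    rows = []
    hists = []
    n_units = None
    for rep, child in enumerate(ss.spawn(n_reps)):
        w_seed, s_seed, n_seed = [
            int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(3)
        ]
        net = build_network(config, seed=w_seed)
        manifest = generate_manifest(
            numerosities, sets, n_images, rng_seed=s_seed,
            image_size=config.input_size,
        )
        if calibrate:
            calib_idx = (
                manifest.table.groupby(["numerosity", "set"])
                .head(calib_per_cell)
                .index.to_numpy()
            )
            calibrate_batch_norm(net, manifest.images[calib_idx])
        acts = forward_record(
            net, manifest.images, layer_index=layer_index, noise=noise,
            seed=n_seed, bn_mode="running",
        )
        n_units = acts.n_units
        _, selective = screen_selectivity(acts, manifest, alpha=alpha)
        frac_sel = len(selective) / acts.n_units
        if len(selective):
            profiles = tuning_profiles(acts, manifest, selective, warn_flat=False)
            prefs = np.array([p.preferred_numerosity for p in profiles])
            frac_zero = float(np.mean(prefs == 0))
            hist = np.array([(prefs == q).sum() for q in numerosities], float)
            variability = response_variability(acts, manifest, profiles)
        else:
            frac_zero, variability = float("nan"), float("nan")
            hist = np.zeros(len(numerosities))
        hists.append(hist)
        rows.append(
            {
                "rep": rep,
                "weights_seed": w_seed,
                "stimulus_seed": s_seed,
                "noise_seed": n_seed,
                "n_selective": int(len(selective)),
                "fraction_selective": frac_sel,
                "fraction_zero_preferring": frac_zero,
                "response_variability": variability,
            }
        )
    per_rep = pd.DataFrame(rows)

    def _mse(col):
        v = per_rep[col].to_numpy()
        se = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0
        return float(v.mean()), float(se)

    fs, fs_se = _mse("fraction_selective")
    fz, fz_se = _mse("fraction_zero_preferring")
    rv, rv_se = _mse("response_variability")
    return SelectivityScreenSummary(
        n_units_total=int(n_units),
        n_reps=n_reps,
        fraction_selective=fs,
        fraction_selective_se=fs_se,
        fraction_zero_preferring=fz,
        fraction_zero_preferring_se=fz_se,
        preferred_histogram=np.stack(hists).mean(axis=0),
        numerosities=numerosities,
        response_variability=rv,
        response_variability_se=rv_se,
        per_rep=per_rep,
    )
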