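"""Intra-cell transcriptional variability and stage-comparison machinery.

The noise-to-signal measure is the Fano factor of a cell's intensity time
series: variance divided by the mean.  Variance uses the population divisor
(n) by default -- the trace is the full observation, not a sample from a
longer stationary record -- with ``ddof=1`` available as a switch.  Cells
whose mean intensity is not positive have an undefined Fano factor and are
excluded from Fano analyses (with a logged count).

Stage comparisons use bootstrap percentile confidence intervals for medians
and two-sided Mann-Whitney U tests; no multiple-testing correction is applied
by default (a Benjamini-Hochberg option exists but is off).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SingularFitError
from .trace import IntensityTrace


@dataclass(frozen=True)
class VariabilityStats:
    mean: float
    variance: float
    fano: float | None  # None when mean <= 0 (undefined, not an error)


def fano_factor(trace_or_values, ddof: int = 0) -> VariabilityStats:
    """Variance-to-mean ratio of a cell's intensity samples."""
    y = (
        trace_or_values.intensities
        if isinstance(trace_or_values, IntensityTrace)
        else np.asarray(trace_or_values, dtype=float)
    )
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    mu = float(np.mean(y))
    var = float(np.var(y, ddof=ddof))
    return VariabilityStats(mean=mu, variance=var, fano=var / mu if mu > 0 else None)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int
    slope_stderr: float = np.nan


def _ols(x, y) -> RegressionResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise SingularFitError("all x values identical; slope is not identifiable")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
        slope_stderr=float(res.stderr),
    )


def fano_mean_regression(mean_intensities, fanos) -> RegressionResult:
    """OLS of Fano factor on mean spot intensity for the cells of one stage.

    The slope measures how steeply noise grows with expression; comparing
    stage slopes to the pooled slope localises where transcription is
    relatively variable.
    """
    m = np.asarray(mean_intensities, dtype=float)
    f = np.asarray(fanos, dtype=float)
    ok = np.isfinite(f)
    return _ols(m[ok], f[ok])


def relative_variability(stage_slopes: dict, pooled_slope: float) -> dict:
    """Per-stage ratio of the stage's Fano-mean slope to the pooled slope."""
    if pooled_slope == 0:
        raise ValueError("pooled slope must be non-zero")
    return {k: v / pooled_slope for k, v in stage_slopes.items()}


def explained_variance(on_fractions, mean_intensities) -> float:
    """r^2 of mean spot intensity regressed on ON fraction."""
    return _ols(on_fractions, mean_intensities).r_squared


@dataclass(frozen=True)
class BootstrapCI:
    point_median: float
    ci_low: float
    ci_high: float
    n_resamples: int
    subsample_n: int
    seed: int | None


def bootstrap_median_ci(
    values,
    subsample_n: int = 31,
    n_resamples: int = 10_000,
    seed=None,
    ci: float = 95.0,
) -> BootstrapCI:
    """Percentile bootstrap CI for the median.

    Each resample draws ``subsample_n`` values with replacement (the default
    31 matches a smallest-group size so stages are compared at equal
    resampling depth); the CI is the (2.5, 97.5) percentile pair of the
    resampled medians.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be non-empty")
    rng = np.random.default_rng(seed)
    draws = rng.choice(v, size=(n_resamples, subsample_n), replace=True)
    medians = np.median(draws, axis=1)
    alpha = (100.0 - ci) / 2
    lo, hi = np.percentile(medians, [alpha, 100.0 - alpha])
    return BootstrapCI(
        point_median=float(np.median(v)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_resamples=n_resamples,
        subsample_n=subsample_n,
        seed=seed,
    )


DEFAULT_STAGE_PAIRS = (("DS1", "DS4"), ("DS4", "DS6"))


def compare_stages(groups: dict, pairs=DEFAULT_STAGE_PAIRS, correct: bool = False) -> pd.DataFrame:
    """Two-sided Mann-Whitney U tests between stage groups.

    ``groups`` maps stage label to an array of per-cell values.  No
    multiple-testing correction by default; ``correct=True`` adds
    Benjamini-Hochberg adjusted p-values.
    """
    rows = []
    for a, b in pairs:
        for g in (a, b):
            if g not in groups or len(np.asarray(groups[g])) < 3:
                raise ValueError(f"group {g} missing or has fewer than 3 values")
        u, p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        rows.append({"group_a": a, "group_b": b, "U": float(u), "p_value": float(p)})
    out = pd.DataFrame(rows)
    if correct and len(out):
        p = out["p_value"].to_numpy()
        order = np.argsort(p)
        ranked = np.empty_like(p)
        m = len(p)
        adj = np.minimum.accumulate((p[order] * m / (np.arange(m) + 1))[::-1])[::-1]
        ranked[order] = np.minimum(adj, 1.0)
        out["p_adjusted"] = ranked
    return out


@dataclass(frozen=True)
class StageVariability:
    """Bundle of per-stage variability results used by the pipeline."""

    stage_summary: pd.DataFrame = field(repr=False)
    pooled_regression: RegressionResult = None
    tests: pd.DataFrame = field(repr=False, default=None)
    n_excluded_fano: int = 0


def stage_variability(
    summaries: pd.DataFrame,
    stages: pd.Series,
    fanos: pd.Series,
    subsample_n: int = 31,
    n_resamples: int = 10_000,
    seed=None,
) -> StageVariability:
    """Per-stage medians with bootstrap CIs, Fano-mean slopes and slope ratios.

    ``summaries`` needs columns mean_intensity and on_fraction aligned with
    ``stages`` and ``fanos``.  Stages with too few cells for a regression get
    NaN slopes.
    """
    df = summaries.copy()
    df["stage"] = np.asarray(stages)
    df["fano"] = np.asarray(fanos, dtype=float)
    n_excluded = int((~np.isfinite(df["fano"])).sum())
    ok = df[np.isfinite(df["fano"])]
    pooled = _ols(ok["mean_intensity"], ok["fano"]) if len(ok) >= 3 else None
    rows = []
    rng = np.random.default_rng(seed)
    for stage, grp in df.groupby("stage", sort=True):
        ci = bootstrap_median_ci(
            grp["mean_intensity"].to_numpy(),
            subsample_n=subsample_n,
            n_resamples=n_resamples,
            seed=int(rng.integers(2**31 - 1)),
        )
        grp_ok = grp[np.isfinite(grp["fano"])]
        if len(grp_ok) >= 3 and np.ptp(grp_ok["mean_intensity"].to_numpy()) > 0:
            reg = _ols(grp_ok["mean_intensity"], grp_ok["fano"])
            slope, r2 = reg.slope, reg.r_squared
        else:
            slope, r2 = np.nan, np.nan
        rows.append(
            {
                "stage": stage,
                "n": len(grp),
                "median_mean_intensity": ci.point_median,
                "ci_low": ci.ci_low,
                "ci_high": ci.ci_high,
                "median_on_fraction": float(grp["on_fraction"].median()),
                "fano_slope": slope,
                "fano_r_squared": r2,
            }
        )
    table = pd.DataFrame(rows)
    if pooled is not None and pooled.slope != 0:
        table["slope_ratio"] = table["fano_slope"] / pooled.slope
    else:
        table["slope_ratio"] = np.nan
    groups = {s: g["mean_intensity"].to_numpy() for s, g in df.groupby("stage")}
    try:
        tests = compare_stages(groups)
    except ValueError:
        tests = pd.DataFrame(columns=["group_a", "group_b", "U", "p_value"])
    return StageVariability(
        stage_summary=table,
        pooled_regression=pooled,
        tests=tests,
        n_excluded_fano=n_excluded,
    )
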