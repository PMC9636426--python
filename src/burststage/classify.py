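"""Per-cell bursting-behaviour classification.

The duration-output plane (total ON duration versus total transcriptional
output per cell) is smoothed with robust LOWESS.  A step-change (inflection)
in the smoothed gradient separates 'High ON' cells -- nearly continuously
active, transcribing with elevated amplitude -- from 'Low ON' cells.  A
quadratic fitted to the Low-ON part of the smoothed curve extrapolates the
expected output of *basal-amplitude* bursting over the full duration range;
each cell's residual from that expectation, normalised by its ON duration,
is its basal-amplitude deviation score.  Scores beyond one standard
deviation above the Low-ON median mark high-amplitude bursting, giving three
behaviours: basal amplitude (any ON level), high-ON high-amplitude, and
low-ON high-amplitude (sporadic strong bursts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .errors import (
    CannotCalibrateError,
    InsufficientDataError,
    NoInflectionError,
    SingularFitError,
)

HIGH_ON, LOW_ON = "HIGH_ON", "LOW_ON"
BASAL, HIGH_AMPLITUDE = "BASAL", "HIGH_AMPLITUDE"
CLASS_BASAL = "BASAL"
CLASS_HIGH_ON = "HIGH_ON_HIGH_AMP"
CLASS_LOW_ON = "LOW_ON_HIGH_AMP"
CLASS_LABELS = (CLASS_BASAL, CLASS_HIGH_ON, CLASS_LOW_ON)

#: map (on_group, amplitude_group) -> final class
_FINAL = {
    (HIGH_ON, BASAL): CLASS_BASAL,
    (LOW_ON, BASAL): CLASS_BASAL,
    (HIGH_ON, HIGH_AMPLITUDE): CLASS_HIGH_ON,
    (LOW_ON, HIGH_AMPLITUDE): CLASS_LOW_ON,
}


@dataclass(frozen=True)
class DurationOutputCurve:
    grid: np.ndarray = field(repr=False)  # sorted unique ON durations (min)
    smoothed_output: np.ndarray = field(repr=False)
    span: float = 0.3


def fit_duration_output_curve(
    on_durations, outputs, span: float = 0.3, robust_iters: int = 3
) -> DurationOutputCurve:
    """Robust LOWESS (local linear, tricube weights, bisquare reweighting)
    of output on ON duration, evaluated at the sorted unique durations."""
    d = np.asarray(on_durations, dtype=float)
    o = np.asarray(outputs, dtype=float)
    if d.size < 20:
        raise InsufficientDataError("need at least 20 cells for the duration-output curve")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    grid = np.unique(d)
    with np.errstate(invalid="ignore", divide="ignore"):  # statsmodels 0/0 on tie-heavy x
        smoothed = sm_lowess(o, d, frac=span, it=robust_iters, xvals=grid)
    return DurationOutputCurve(grid=grid, smoothed_output=np.asarray(smoothed), span=span)


def _moving_average(v, w):
    if w <= 1:
        return v
    kernel = np.ones(w) / w
    pad = w // 2
    padded = np.concatenate([np.full(pad, v[0]), v, np.full(w - 1 - pad, v[-1])])
    return np.convolve(padded, kernel, mode="valid")


def find_inflection(
    curve: DurationOutputCurve,
    window_min: float | None = None,
    smooth_window: int = 5,
    min_step_fraction: float = 0.05,
) -> tuple[float, float]:
    """Locate the step-change in the gradient of the smoothed curve.

    The finite-difference gradient is lightly smoothed; the inflection is the
    grid point with the largest positive second difference.  A flat or
    uniformly sloped curve (gradient range below ``min_step_fraction`` of the
    gradient scale, or no positive second difference) has no step and raises
    :class:`NoInflectionError`.

    Returns (inflection_duration, inflection_fraction) where the fraction is
    relative to ``window_min`` (default: the largest observed duration).
    """
    g = curve.grid
    if g.size < 10:
        raise ValueError("need at least 10 grid points")
    grad = np.gradient(curve.smoothed_output, g)
    grad_s = _moving_average(grad, min(smooth_window, g.size // 2 * 2 - 1))
    scale = max(np.max(np.abs(grad_s)), 1e-12)
    if np.ptp(grad_s) < min_step_fraction * scale:
        raise NoInflectionError("gradient is flat/uniform; no step-change to locate")
    dd = np.diff(grad_s)
    # the inflection lives in the grid interior: boundary gradient estimates
    # are one-sided and unreliable, so exclude a smoothing-window margin
    margin = max(2, smooth_window // 2 + 1)
    interior = slice(margin, max(margin + 1, dd.size - margin))
    if np.max(dd[interior]) <= 0:
        raise NoInflectionError("gradient never increases; no upward step-change")
    idx = margin + int(np.argmax(dd[interior])) + 1  # where the higher gradient begins
    inflection = float(g[idx])
    window = float(window_min) if window_min is not None else float(g[-1])
    return inflection, inflection / window


def split_high_low_on(on_durations, inflection_duration: float) -> np.ndarray:
    """HIGH_ON iff duration strictly above the inflection (ties are LOW_ON)."""
    d = np.asarray(on_durations, dtype=float)
    return np.where(d > inflection_duration, HIGH_ON, LOW_ON)


@dataclass(frozen=True)
class BasalQuadratic:
    """Least-squares quadratic through the Low-ON segment of the LOWESS grid."""

    coefficients: tuple[float, float, float]  # (a, b, c): a*d^2 + b*d + c
    fit_domain: tuple[float, float]

    def __call__(self, durations):
        a, b, c = self.coefficients
        d = np.asarray(durations, dtype=float)
        return a * d**2 + b * d + c


def fit_basal_quadratic(durations, outputs, through_origin: bool = True) -> BasalQuadratic:
    """Quadratic basal-output expectation over ON duration.

    By default the fit is anchored at the origin (c = 0): a gene with zero ON
    duration produces exactly zero output, and a free intercept lets noise at
    the short-duration end of the smoothed curve leak into the constant term,
    which the 1/duration normalisation of the deviation score then amplifies
    without bound as duration -> 0.  ``through_origin=False`` gives the
    unconstrained least-squares quadratic.
    """
    d = np.asarray(durations, dtype=float)
    o = np.asarray(outputs, dtype=float)
    if np.unique(d).size < 3:
        raise SingularFitError("need at least 3 distinct durations for a quadratic")
    if through_origin:
        design = np.column_stack([d**2, d])
        coef, _, rank, _ = np.linalg.lstsq(design, o, rcond=None)
        if rank < 2:
            raise SingularFitError("rank-deficient design for the quadratic fit")
        coeffs = (float(coef[0]), float(coef[1]), 0.0)
    else:
        coeffs = tuple(float(c) for c in np.polyfit(d, o, deg=2))
    return BasalQuadratic(
        coefficients=coeffs,
        fit_domain=(float(d.min()), float(d.max())),
    )


@dataclass(frozen=True)
class ClassificationResult:
    table: pd.DataFrame = field(repr=False)
    amplitude_threshold: float = np.nan
    inflection_duration: float = np.nan
    inflection_fraction: float = np.nan
    basal_quadratic: BasalQuadratic = None
    curve: DurationOutputCurve = None


def deviation_scores(on_durations, outputs, quad: BasalQuadratic) -> np.ndarray:
    """Basal-amplitude deviation score: output residual from the basal
    expectation, per minute of ON time.  Silent cells (duration 0) score 0:
    a gene that never fires exhibits no amplitude at all."""
    d = np.asarray(on_durations, dtype=float)
    o = np.asarray(outputs, dtype=float)
    scores = np.zeros_like(d)
    nz = d > 0
    scores[nz] = (o[nz] - quad(d[nz])) / d[nz]
    return scores


def classify_scores(scores, on_groups, on_durations) -> tuple[pd.DataFrame, float]:
    """Threshold deviation scores at Low-ON median + 1 SD and assign classes."""
    scores = np.asarray(scores, dtype=float)
    on_groups = np.asarray(on_groups)
    d = np.asarray(on_durations, dtype=float)
    low = scores[on_groups == LOW_ON]
    if low.size == 0:
        raise CannotCalibrateError("no Low-ON cells to calibrate the amplitude threshold")
    thresh = float(np.median(low) + np.std(low))
    amp = np.where(scores > thresh, HIGH_AMPLITUDE, BASAL)
    amp[d == 0] = BASAL
    final = np.array([_FINAL[(g, a)] for g, a in zip(on_groups, amp)])
    table = pd.DataFrame(
        {
            "on_group": on_groups,
            "deviation_score": scores,
            "amplitude_group": amp,
            "final_class": final,
        }
    )
    return table, thresh


def classify_cells(
    cells: pd.DataFrame,
    span: float = 0.3,
    window_min: float | None = None,
) -> ClassificationResult:
    """End-to-end behaviour classification.

    ``cells`` needs columns cell_id, on_duration, output (and optionally
    stage).  Fits the LOWESS curve, finds the inflection, splits High/Low ON,
    fits the basal quadratic to the Low-ON LOWESS points, scores every cell
    and thresholds at Low-ON median + 1 SD.
    """
    d = cells["on_duration"].to_numpy(float)
    o = cells["output"].to_numpy(float)
    curve = fit_duration_output_curve(d, o, span=span)
    inflection, frac = find_inflection(curve, window_min=window_min)
    on_groups = split_high_low_on(d, inflection)
    low_grid = curve.grid <= inflection
    quad = fit_basal_quadratic(curve.grid[low_grid], curve.smoothed_output[low_grid])
    scores = deviation_scores(d, o, quad)
    table, thresh = classify_scores(scores, on_groups, d)
    out = cells.reset_index(drop=True).copy()
    out = pd.concat([out, table], axis=1)
    return ClassificationResult(
        table=out,
        amplitude_threshold=thresh,
        inflection_duration=inflection,
        inflection_fraction=frac,
        basal_quadratic=quad,
        curve=curve,
    )


def stage_proportions(stages, final_classes, stage_labels=None) -> pd.DataFrame:
    """Per-stage fractions of the three behaviours (rows sum to 1).

    Stages with no cells get NaN fractions and are flagged undefined.
    Counts are reported alongside as ``n``.
    """
    stages = np.asarray(stages)
    final_classes = np.asarray(final_classes)
    labels = (
        sorted(np.unique(stages)) if stage_labels is None else list(stage_labels)
    )
    rows = []
    for s in labels:
        sel = stages == s
        n = int(sel.sum())
        row = {"stage": s, "n": n}
        for cls in CLASS_LABELS:
            row[cls] = float((final_classes[sel] == cls).mean()) if n else np.nan
        row["undefined"] = n == 0
        rows.append(row)
    return pd.DataFrame(rows)


def inflection_stability(cells: pd.DataFrame, spans=(0.2, 0.3, 0.4), window_min=None) -> pd.DataFrame:
    """Inflection location across LOWESS spans, reported for robustness."""
    rows = []
    d = cells["on_duration"].to_numpy(float)
    o = cells["output"].to_numpy(float)
    for s in spans:
        try:
            curve = fit_duration_output_curve(d, o, span=s)
            infl, frac = find_inflection(curve, window_min=window_min)
            rows.append({"span": s, "inflection_duration": infl, "inflection_fraction": frac})
        except NoInflectionError:
            rows.append({"span": s, "inflection_duration": np.nan, "inflection_fraction": np.nan})
    return pd.DataFrame(rows)
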