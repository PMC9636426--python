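"""ON/OFF interval extraction and burst statistics from intensity traces.

A trace is treated as a piecewise-linear interpolant between its samples.
ON intervals are the maximal intervals on which the interpolant is at or
above the ON threshold, with crossing times solved exactly on each segment
(a sample exactly at the threshold counts as ON, making intervals closed and
the threshold response right-continuous).  Burst size is the area between
the interpolant and the threshold over an interval; a burst is "complete"
when the trace is below threshold immediately before and after it, so
intervals touching the observation window edges are incomplete -- they are
excluded from burst duration/size distributions but still contribute to the
cell's transcriptional output.

Also here: the frame-interval optimisation used to choose an imaging rate --
traces are decimated to a coarser interval, interpolated back onto the raw
grid, and compared by root-mean-squared error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trace import IntensityTrace


@dataclass(frozen=True)
class OnIntervals:
    """Ordered disjoint [start, end] intervals where the trace is ON."""

    intervals: tuple  # of (start, end) pairs, minutes
    window: tuple  # (t_first, t_last)

    @property
    def total_duration(self) -> float:
        return float(sum(e - s for s, e in self.intervals))


@dataclass(frozen=True)
class Burst:
    start: float
    end: float
    size: float  # a.u. * min above threshold
    complete: bool

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class BurstSummary:
    cell_id: str
    on_fraction: float
    on_duration: float
    output: float
    n_complete_bursts: int
    mean_intensity: float
    fano: float | None = None


def _crossing(t0, t1, y0, y1, threshold):
    return t0 + (threshold - y0) * (t1 - t0) / (y1 - y0)


def find_on_intervals(trace: IntensityTrace, threshold: float) -> OnIntervals:
    """Exact ON intervals of the piecewise-linear interpolant.

    Zero-length touches (an isolated sample exactly at threshold with both
    neighbours below) are dropped: they have zero measure and no burst can
    have zero duration.
    """
    t, y = trace.times, trace.intensities
    above = y >= threshold
    intervals = []
    start = t[0] if above[0] else None
    for i in range(len(t) - 1):
        if start is None and above[i + 1]:
            # upward crossing: y[i] < threshold <= y[i+1]
            start = _crossing(t[i], t[i + 1], y[i], y[i + 1], threshold)
        elif start is not None and not above[i + 1]:
            # downward crossing: y[i] >= threshold > y[i+1]
            end = _crossing(t[i], t[i + 1], y[i], y[i + 1], threshold)
            if end > start:
                intervals.append((float(start), float(end)))
            start = None
    if start is not None and t[-1] > start:
        intervals.append((float(start), float(t[-1])))
    return OnIntervals(intervals=tuple(intervals), window=(float(t[0]), float(t[-1])))


def _interval_size(trace: IntensityTrace, threshold: float, start: float, end: float) -> float:
    """Trapezoid area of (interpolant - threshold) over [start, end]."""
    t, y = trace.times, trace.intensities
    inner = t[(t > start) & (t < end)]
    knots = np.concatenate([[start], inner, [end]])
    vals = np.interp(knots, t, y) - threshold
    return float(np.trapezoid(np.clip(vals, 0.0, None), knots))


def summarize_bursts(trace: IntensityTrace, threshold: float):
    """Per-cell burst summary and the list of individual bursts.

    ``output`` sums the area above threshold over all ON intervals, complete
    or not; ``on_fraction`` uses the total elapsed time of the trace as its
    denominator.
    """
    on = find_on_intervals(trace, threshold)
    t0, t1 = on.window
    bursts = []
    output = 0.0
    for s, e in on.intervals:
        size = _interval_size(trace, threshold, s, e)
        complete = (s > t0) and (e < t1)
        bursts.append(Burst(start=s, end=e, size=size, complete=complete))
        output += size
    on_duration = on.total_duration
    summary = BurstSummary(
        cell_id=trace.cell_id,
        on_fraction=on_duration / (t1 - t0),
        on_duration=on_duration,
        output=output,
        n_complete_bursts=sum(b.complete for b in bursts),
        mean_intensity=float(np.mean(trace.intensities)),
    )
    return summary, bursts


def summaries_frame(traces, threshold: float) -> pd.DataFrame:
    """Burst summaries for many traces as one table."""
    rows = []
    for tr in traces:
        s, _ = summarize_bursts(tr, threshold)
        rows.append(
            {
                "cell_id": s.cell_id,
                "on_fraction": s.on_fraction,
                "on_duration": s.on_duration,
                "output": s.output,
                "n_complete_bursts": s.n_complete_bursts,
                "mean_intensity": s.mean_intensity,
            }
        )
    return pd.DataFrame(rows)


def bursts_frame(traces, threshold: float) -> pd.DataFrame:
    rows = []
    for tr in traces:
        _, bb = summarize_bursts(tr, threshold)
        for b in bb:
            rows.append(
                {
                    "cell_id": tr.cell_id,
                    "start": b.start,
                    "end": b.end,
                    "duration": b.duration,
                    "size": b.size,
                    "complete": b.complete,
                }
            )
    return pd.DataFrame(rows, columns=["cell_id", "start", "end", "duration", "size", "complete"])


def threshold_sweep(traces, thresholds) -> pd.DataFrame:
    """Total complete-burst count across all traces at each threshold.

    Counting complete bursts across a wide threshold range peaks at an
    intermediate value: too low and the trace never switches OFF, too high
    and it never switches ON.  The returned frame carries an ``is_peak``
    column marking the argmax.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("threshold grid must be non-empty")
    counts = np.zeros(thresholds.size, dtype=int)
    for tr in traces:
        for j, thr in enumerate(thresholds):
            s, _ = summarize_bursts(tr, thr)
            counts[j] += s.n_complete_bursts
    out = pd.DataFrame({"threshold": thresholds, "n_complete_bursts": counts})
    out["is_peak"] = False
    out.loc[int(np.argmax(counts)), "is_peak"] = True
    return out


@dataclass(frozen=True)
class SubsampleComparison:
    interval: float
    n: int
    rmse: float
    y_raw: np.ndarray = field(repr=False)
    y_sub: np.ndarray = field(repr=False)


def subsample_rmse(trace: IntensityTrace, interval: float) -> SubsampleComparison:
    """Information loss of imaging at a coarser frame interval.

    Every k-th sample is kept (k = interval / native spacing, rounded to the
    nearest achievable multiple), linearly interpolated back onto the raw
    time grid (held constant past the last kept sample), and compared to the
    raw trace by RMSE over all raw points:

        RMSE = sqrt( sum_1^n (y_sub - y_raw)^2 / n )
    """
    t, y = trace.times, trace.intensities
    native = float(np.median(np.diff(t)))
    if interval < native - 1e-9:
        raise ValueError("interval must be at least the native sample spacing")
    k = max(1, int(round(interval / native)))
    y_sub = np.interp(t, t[::k], y[::k])
    rmse = float(np.sqrt(np.mean((y_sub - y) ** 2)))
    return SubsampleComparison(interval=interval, n=len(t), rmse=rmse, y_raw=y, y_sub=y_sub)


@dataclass(frozen=True)
class IntervalSelection:
    interval: float
    warning: bool
    table: pd.DataFrame = field(repr=False)


def select_interval(traces, candidate_intervals, rmse_budget: float) -> IntervalSelection:
    """Largest candidate interval whose median per-cell RMSE fits the budget.

    If no candidate satisfies the budget the smallest candidate is returned
    with ``warning=True``.  The full median-RMSE-versus-interval table is
    attached either way.
    """
    candidates = sorted(float(c) for c in candidate_intervals)
    if not candidates:
        raise ValueError("candidate_intervals must be non-empty")
    medians = []
    for c in candidates:
        vals = [subsample_rmse(tr, c).rmse for tr in traces]
        medians.append(float(np.median(vals)))
    table = pd.DataFrame({"interval": candidates, "median_rmse": medians})
    ok = [c for c, m in zip(candidates, medians) if m <= rmse_budget]
    if ok:
        return IntervalSelection(interval=max(ok), warning=False, table=table)
    return IntervalSelection(interval=candidates[0], warning=True, table=table)
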