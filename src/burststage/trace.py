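"""Per-cell spot-intensity time series: the atom of all burst analysis."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class IntensityTrace:
    """A single cell's nascent-transcription spot-intensity time series.

    Parameters
    ----------
    cell_id
        Identifier carried through every downstream table.
    times
        Sample times in minutes, strictly increasing, >= 2 samples.
    intensities
        Spot intensities in arbitrary units.  Background-corrected values may
        legitimately be negative; they are kept as-is.
    """

    cell_id: str
    times: np.ndarray = field(repr=False)
    intensities: np.ndarray = field(repr=False)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise ValueError("times and intensities must be 1-D and equal length")
        if t.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)

    @property
    def duration(self) -> float:
        """Total elapsed time of the trace in minutes."""
        return float(self.times[-1] - self.times[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_id, "time_min": self.times, "intensity_au": self.intensities}
        )


def traces_to_frame(traces) -> pd.DataFrame:
    """Stack traces into the long-format interchange table."""
    return pd.concat([tr.to_frame() for tr in traces], ignore_index=True)


def traces_from_frame(df: pd.DataFrame) -> list[IntensityTrace]:
    """Rebuild traces from a long-format table (cell_id, time_min, intensity_au)."""
    out = []
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("time_min")
        out.append(
            IntensityTrace(str(cid), grp["time_min"].to_numpy(), grp["intensity_au"].to_numpy())
        )
    return out


def write_traces_csv(traces, path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces_csv(path) -> list[IntensityTrace]:
    return traces_from_frame(pd.read_csv(path))
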