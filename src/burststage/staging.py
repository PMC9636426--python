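"""Two-marker differentiation staging.

Each cell's CD71 and Ter119 surface-marker intensities are compressed with an
asinh transform, projected onto the nearest point of a family of discretised
marker-trajectory curves, and the arc-length fraction of that point becomes
the cell's position on a one-dimensional differentiation axis in [0, 1].
Positions are then binned into six contiguous stages DS1-DS6.

The curve family shipped here is a package default: trajectories of this kind
are defined empirically per experiment, so the control points (and the stage
boundaries) are config-overridable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError

DEFAULT_COFACTOR = 150.0
DEFAULT_P = 10_000
STAGE_LABELS = ("DS1", "DS2", "DS3", "DS4", "DS5", "DS6")
#: Equal sextiles of the axis; real analyses set these per experiment.
DEFAULT_STAGE_BOUNDARIES = (1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6)


def transform_markers(cd71, ter119, cofactor: float = DEFAULT_COFACTOR):
    """Compress raw marker intensities with ``asinh(x / cofactor)``.

    A one-parameter stand-in for the biexponential/logicle display scale used
    for flow-cytometry data: monotone, invertible, ~linear near zero and
    logarithmic for ``x >> cofactor``.  Negative intensities are permitted.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return np.arcsinh(np.asarray(cd71, dtype=float) / cofactor), np.arcsinh(
        np.asarray(ter119, dtype=float) / cofactor
    )


def inverse_transform_markers(cd71_t, ter119_t, cofactor: float = DEFAULT_COFACTOR):
    """Exact inverse of :func:`transform_markers`."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return np.sinh(np.asarray(cd71_t, dtype=float)) * cofactor, np.sinh(
        np.asarray(ter119_t, dtype=float)
    ) * cofactor


@dataclass(frozen=True)
class DifferentiationCurve:
    """A discretised trajectory in transformed (CD71', Ter119') space.

    ``points`` holds P vertices equally spaced in cumulative arc length;
    ``fractions[i]`` is the arc-length fraction (0..1) of point i.
    """

    curve_id: str
    control_points: np.ndarray = field(repr=False)
    points: np.ndarray = field(repr=False)
    fractions: np.ndarray = field(repr=False)

    def point_at(self, fraction: float) -> np.ndarray:
        """Interpolated curve point at a given arc-length fraction."""
        f = float(fraction)
        if not 0.0 <= f <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        x = np.interp(f, self.fractions, self.points[:, 0])
        y = np.interp(f, self.fractions, self.points[:, 1])
        return np.array([x, y])


def build_curve(control_points, P: int = DEFAULT_P, curve_id: str = "curve") -> DifferentiationCurve:
    """Resample a polyline to ``P`` points equally spaced in arc length."""
    cp = np.asarray(control_points, dtype=float)
    if cp.ndim != 2 or cp.shape[0] < 2 or cp.shape[1] != 2:
        raise ValueError("control_points must be an (n >= 2, 2) array")
    if P < 2:
        raise ValueError("P must be >= 2")
    seg = np.linalg.norm(np.diff(cp, axis=0), axis=1)
    if np.any(seg == 0):
        raise ValueError("duplicate consecutive control points collapse arc length")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    target = np.linspace(0.0, total, P)
    pts = np.column_stack(
        [np.interp(target, cum, cp[:, 0]), np.interp(target, cum, cp[:, 1])]
    )
    return DifferentiationCurve(curve_id, cp, pts, target / total)


# Default control points in transformed (asinh, cofactor 150) space.  Three
# trajectories share the canonical CD71-then-Ter119 shape but start from low,
# medium and high CD71 levels, covering the spread of CD71 staining seen in
# Ter119-low cells.  The middle curve is the canonical one the synthetic
# marker generator follows.
DEFAULT_CURVE_CONTROL_POINTS = {
    "low_cd71": [(0.2, 0.15), (3.4, 0.3), (4.6, 0.8), (5.0, 3.0), (4.4, 5.0)],
    "mid_cd71": [(0.5, 0.2), (4.0, 0.4), (5.0, 1.0), (5.3, 3.2), (4.6, 5.2)],
    "high_cd71": [(1.0, 0.25), (4.6, 0.5), (5.4, 1.2), (5.6, 3.4), (4.8, 5.4)],
}
CANONICAL_CURVE_ID = "mid_cd71"


def default_curve_set(P: int = DEFAULT_P) -> list[DifferentiationCurve]:
    return [
        build_curve(cp, P=P, curve_id=name)
        for name, cp in DEFAULT_CURVE_CONTROL_POINTS.items()
    ]


def build_curve_set(families: dict, P: int = DEFAULT_P) -> list[DifferentiationCurve]:
    """Build several curves from ``{curve_id: control_points}``."""
    return [build_curve(cp, P=P, curve_id=name) for name, cp in families.items()]


def canonical_curve(P: int = DEFAULT_P) -> DifferentiationCurve:
    """The curve the synthetic marker generator places noiseless cells on."""
    return build_curve(
        DEFAULT_CURVE_CONTROL_POINTS[CANONICAL_CURVE_ID], P=P, curve_id=CANONICAL_CURVE_ID
    )


def save_curves_json(curves, path) -> None:
    payload = {c.curve_id: np.asarray(c.control_points).tolist() for c in curves}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_curves_json(path, P: int = DEFAULT_P) -> list[DifferentiationCurve]:
    with open(path) as fh:
        payload = json.load(fh)
    return build_curve_set(payload, P=P)


def project_cells(markers_t: np.ndarray, curves, chunk: int = 256) -> pd.DataFrame:
    """Project transformed marker pairs onto the nearest curve point.

    Nearest by Euclidean distance over all discretised points of all curves;
    ties are broken by lowest curve index then lowest point index (the order
    of ``curves`` and of points within a curve), which is what a first-minimum
    argmin over the concatenated point list yields.

    Returns a DataFrame with columns position, nearest_curve, distance.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("curve set must be non-empty")
    pts = np.concatenate([c.points for c in curves], axis=0)
    fracs = np.concatenate([c.fractions for c in curves])
    curve_ids = np.concatenate(
        [np.full(len(c.points), i, dtype=int) for i, c in enumerate(curves)]
    )
    X = np.atleast_2d(np.asarray(markers_t, dtype=float))
    positions = np.empty(len(X))
    dists = np.empty(len(X))
    which = np.empty(len(X), dtype=int)
    for lo in range(0, len(X), chunk):
        xs = X[lo : lo + chunk]
        d2 = ((xs[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        idx = np.argmin(d2, axis=1)  # first minimum -> documented tie-break
        positions[lo : lo + chunk] = fracs[idx]
        dists[lo : lo + chunk] = np.sqrt(d2[np.arange(len(xs)), idx])
        which[lo : lo + chunk] = curve_ids[idx]
    return pd.DataFrame(
        {
            "position": positions,
            "nearest_curve": [curves[i].curve_id for i in which],
            "distance": dists,
        }
    )


def bin_stages(positions, boundaries=DEFAULT_STAGE_BOUNDARIES) -> np.ndarray:
    """Bin axis positions into DS1-DS6 with half-open bins.

    Bins are [0, b1), [b1, b2), ..., [b5, 1]: a position exactly at a
    boundary belongs to the later stage.
    """
    b = np.asarray(boundaries, dtype=float)
    if b.size != 5 or not np.all(np.diff(b) > 0) or b[0] <= 0 or b[-1] >= 1:
        raise ValueError("boundaries must be 5 strictly increasing cut points in (0, 1)")
    pos = np.asarray(positions, dtype=float)
    idx = np.searchsorted(b, pos, side="right")
    return np.asarray(STAGE_LABELS)[idx]


def stage_cells(
    cd71,
    ter119,
    curves=None,
    cofactor: float = DEFAULT_COFACTOR,
    boundaries=DEFAULT_STAGE_BOUNDARIES,
    cell_ids=None,
) -> pd.DataFrame:
    """Transform, project and bin in one call; the staging module's main entry."""
    curves = default_curve_set() if curves is None else curves
    c_t, t_t = transform_markers(cd71, ter119, cofactor)
    proj = project_cells(np.column_stack([c_t, t_t]), curves)
    proj.insert(0, "cell_id", cell_ids if cell_ids is not None else np.arange(len(proj)))
    proj["cd71_t"] = c_t
    proj["ter119_t"] = t_t
    proj["stage"] = bin_stages(proj["position"].to_numpy(), boundaries)
    return proj


@dataclass(frozen=True)
class AxisAlignment:
    """A monotone remapping of query positions onto a reference axis."""

    shift: float
    bin_width: float
    correlation: float
    table: pd.DataFrame = field(repr=False)

    def __call__(self, positions):
        return np.clip(np.asarray(positions, dtype=float) - self.shift, 0.0, 1.0)


def _size_profile(positions, sizes, n_bins):
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(positions, edges) - 1, 0, n_bins - 1)
    prof = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() >= 2:
            prof[b] = np.median(sizes[sel])
    # fill gaps by linear interpolation, then a 3-point moving median
    ok = np.isfinite(prof)
    if ok.sum() < max(3, n_bins // 3):
        raise AlignmentError("too few populated position bins to build a size profile")
    centers = (edges[:-1] + edges[1:]) / 2
    prof = np.interp(centers, centers[ok], prof[ok])
    sm = prof.copy()
    sm[1:-1] = np.median(np.column_stack([prof[:-2], prof[1:-1], prof[2:]]), axis=1)
    return centers, sm


def align_axes(
    reference: pd.DataFrame,
    query: pd.DataFrame,
    n_bins: int = 25,
    max_shift: float = 0.3,
    min_correlation: float = 0.5,
) -> AxisAlignment:
    """Align a query differentiation axis to a reference via cell-size profiles.

    Cell size falls (with reproducible wiggles) along erythroid maturation, so
    the median-size-versus-position profile of two datasets of the same
    biology should superimpose after a shift.  Both inputs need columns
    ``position`` and ``size`` with >= 50 cells.  The returned mapping is the
    global shift maximising the Pearson correlation of the binned profiles;
    monotone by construction.
    """
    for name, df in (("reference", reference), ("query", query)):
        if len(df) < 50:
            raise ValueError(f"{name} needs >= 50 cells with position and size")
    bw = 1.0 / n_bins
    _, ref_prof = _size_profile(
        reference["position"].to_numpy(float), reference["size"].to_numpy(float), n_bins
    )
    _, qry_prof = _size_profile(
        query["position"].to_numpy(float), query["size"].to_numpy(float), n_bins
    )
    if np.std(ref_prof) < 1e-9 * max(1.0, abs(np.mean(ref_prof))) or np.std(
        qry_prof
    ) < 1e-9 * max(1.0, abs(np.mean(qry_prof))):
        raise AlignmentError("size profiles are constant; no fluctuation signal to align on")
    kmax = int(round(max_shift / bw))
    rows = []
    for k in range(-kmax, kmax + 1):
        # positive k: query positions sit k bins to the right of reference
        if k >= 0:
            a, b = ref_prof[: len(ref_prof) - k], qry_prof[k:]
        else:
            a, b = ref_prof[-k:], qry_prof[: len(qry_prof) + k]
        if len(a) < 5 or np.std(a) == 0 or np.std(b) == 0:
            corr = -np.inf
        else:
            corr = float(np.corrcoef(a, b)[0, 1])
        rows.append((k * bw, corr))
    table = pd.DataFrame(rows, columns=["shift", "correlation"])
    best = table.loc[table["correlation"].idxmax()]
    if not np.isfinite(best["correlation"]) or best["correlation"] < min_correlation:
        raise AlignmentError(
            f"profile correlation peak {best['correlation']:.3f} below {min_correlation}"
        )
    return AxisAlignment(
        shift=float(best["shift"]),
        bin_width=bw,
        correlation=float(best["correlation"]),
        table=table,
    )
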