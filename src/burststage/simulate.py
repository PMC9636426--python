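"""Synthetic ground-truth generator: telegraph traces, markers, image stacks.

The generator emulates the statistical structure the analysis assumes so every
downstream stage is testable without external data:

* two-state (telegraph) promoter traces sampled at 2.5-min intervals over
  60 min, in three bursting regimes -- basal amplitude, high-ON
  high-amplitude, and low-ON high-amplitude sporadic bursts;
* stage-dependent regime mixtures with high-amplitude continuous bursting
  enriched mid-differentiation and sporadic bursting enriched at the flanks;
* CD71/Ter119 marker trajectories (double-negative -> CD71+ -> double
  positive) with multiplicative lognormal noise, lying exactly on the staging
  module's canonical curve when noiseless;
* small 3D stacks with a GFP-depleted nucleus inside a GFP-bright cytoplasm
  plus a Gaussian nuclear spot, with ground-truth masks.

All quantitative defaults (amplitudes, baseline, noise, rates, mixtures) are
generator calibrations chosen to be qualitatively realistic; they are not
estimates of any real dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .imaging import ImageStack
from .staging import (
    STAGE_LABELS,
    canonical_curve,
    inverse_transform_markers,
)
from .trace import IntensityTrace

REGIMES = ("basal", "high_on_high_amp", "low_on_high_amp")


@dataclass(frozen=True)
class TelegraphParams:
    """Two-state promoter parameters plus the intensity read-out model.

    The promoter switches OFF->ON at ``k_on`` and ON->OFF at ``k_off``
    (both per minute); the stationary ON probability is
    ``k_on / (k_on + k_off)``.  While ON the spot adds ``amplitude``
    arbitrary units on top of ``baseline``; samples carry additive Gaussian
    noise of sd ``noise_sd``.

    Two optional population-heterogeneity knobs make regimes realistic when
    cells are drawn in bulk.  ``on_prob_concentration`` gives each cell its
    own stationary ON probability from a Beta distribution centred on the
    nominal one (total switching rate preserved): cell-to-cell variation in
    burst frequency is pervasive in real populations, and without it every
    cell of a regime would have a nearly identical ON fraction.
    ``amplitude_cv`` draws each cell's amplitude from a unit-mean lognormal
    with that coefficient of variation: real spot amplitudes vary with
    coat-protein levels and locus state, and a population in which every cell
    shares one exact plateau level is a degenerate artefact (it even puts a
    spurious second mode into threshold sweeps).  Both default to "off" for
    single-trace use; population defaults switch them on.
    """

    k_on: float
    k_off: float
    amplitude: float
    baseline: float = 100.0
    noise_sd: float = 0.0
    regime_label: str = "basal"
    on_prob_concentration: float | None = None
    amplitude_cv: float = 0.0

    def __post_init__(self):
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("switching rates must be positive")
        if self.amplitude < 0 or self.noise_sd < 0 or self.amplitude_cv < 0:
            raise ValueError("amplitude, noise_sd and amplitude_cv must be non-negative")

    @property
    def p_on(self) -> float:
        return self.k_on / (self.k_on + self.k_off)


@dataclass(frozen=True)
class SimulatedTrace:
    """A trace plus the promoter-state ground truth behind it."""

    trace: IntensityTrace
    frame_occupancy: np.ndarray = field(repr=False)  # ON fraction of preceding frame
    sample_states: np.ndarray = field(repr=False)  # instantaneous state at samples
    params: TelegraphParams = None


def _simulate_switches(params: TelegraphParams, duration: float, rng):
    """Exact-event continuous-time simulation of the promoter state.

    Returns (event_times, states) where states[i] holds from event_times[i]
    to event_times[i+1] (or to ``duration``).  Initial state is drawn from
    the stationary distribution.
    """
    state = bool(rng.random() < params.p_on)
    times = [0.0]
    states = [state]
    t = 0.0
    while True:
        t += rng.exponential(1.0 / (params.k_off if state else params.k_on))
        if t >= duration:
            break
        state = not state
        times.append(t)
        states.append(state)
    return np.asarray(times), np.asarray(states, dtype=bool)


def simulate_trace(
    params: TelegraphParams,
    duration: float = 60.0,
    frame_interval: float = 2.5,
    seed=None,
    rng=None,
    cell_id: str = "cell",
    instantaneous: bool = False,
) -> SimulatedTrace:
    """Simulate one spot-intensity trace sampled at t = 0, d, 2d, ... <= duration.

    By default the intensity at each sample is ``baseline + amplitude *
    (fraction of the preceding frame spent ON)`` -- mimicking camera
    integration, which produces the intermediate intensities seen in real
    traces.  ``instantaneous=True`` switches to the raw promoter state at the
    sample instant.  The first sample always uses the instantaneous state
    (it has no preceding frame).
    """
    if duration <= 0 or frame_interval <= 0:
        raise ValueError("duration and frame_interval must be positive")
    if duration < frame_interval:
        raise ValueError("duration must be at least one frame interval")
    rng = np.random.default_rng(seed) if rng is None else rng
    ev, st = _simulate_switches(params, duration, rng)
    n = int(np.floor(duration / frame_interval + 1e-9)) + 1
    t_samp = np.arange(n) * frame_interval
    # cumulative ON time at each event boundary
    cum = np.concatenate([[0.0], np.cumsum(np.diff(np.append(ev, duration)) * st)])

    def on_time(ts):
        idx = np.searchsorted(ev, ts, side="right") - 1
        return cum[idx] + (ts - ev[idx]) * st[idx]

    states = st[np.searchsorted(ev, t_samp, side="right") - 1]
    occ = np.empty(n)
    occ[0] = float(states[0])
    occ[1:] = (on_time(t_samp[1:]) - on_time(t_samp[:-1])) / frame_interval
    np.clip(occ, 0.0, 1.0, out=occ)  # guard float rounding at the ends
    drive = states.astype(float) if instantaneous else occ
    y = params.baseline + params.amplitude * drive
    if params.noise_sd > 0:
        y = y + rng.normal(0.0, params.noise_sd, size=n)
    return SimulatedTrace(
        IntensityTrace(cell_id, t_samp, y), occ, states, params
    )


# --- default regime calibration -------------------------------------------
# ON threshold-relative baseline 100 a.u., basal amplitude 500, high
# amplitude 1200 (ratio 2.4), measurement noise sd 60.  Basal switching is
# stage dependent (ON probability rises to ~0.74 mid-differentiation and
# falls to ~0.30 late); the high-amplitude regimes keep fixed near-continuous
# (~0.95) or sporadic (~0.14) ON probabilities.
BASELINE = 100.0
BASAL_AMPLITUDE = 500.0
HIGH_AMPLITUDE = 1200.0
NOISE_SD = 60.0
_BASAL_TOTAL_RATE = 0.8  # 1/min; mean dwell ~2.5 min at p=0.5
_BASAL_P_BY_STAGE = {"DS1": 0.40, "DS2": 0.62, "DS3": 0.75, "DS4": 0.68, "DS5": 0.48, "DS6": 0.30}
#: regime mixture weights per stage: basal everywhere dominant, sporadic
#: high-amplitude bursting enriched at DS1-2 and DS5, continuous
#: high-amplitude bursting enriched at DS3-4.
_REGIME_WEIGHTS = {
    "DS1": (0.75, 0.05, 0.20),
    "DS2": (0.73, 0.10, 0.17),
    "DS3": (0.72, 0.20, 0.08),
    "DS4": (0.72, 0.20, 0.08),
    "DS5": (0.74, 0.10, 0.16),
    "DS6": (0.80, 0.08, 0.12),
}


def _regime_params(stage: str) -> dict:
    p_basal = _BASAL_P_BY_STAGE[stage]
    return {
        "basal": TelegraphParams(
            k_on=_BASAL_TOTAL_RATE * p_basal,
            k_off=_BASAL_TOTAL_RATE * (1 - p_basal),
            amplitude=BASAL_AMPLITUDE,
            baseline=BASELINE,
            noise_sd=NOISE_SD,
            regime_label="basal",
            on_prob_concentration=2.0,
            amplitude_cv=0.25,
        ),
        "high_on_high_amp": TelegraphParams(
            k_on=2.0,
            k_off=0.1,
            amplitude=HIGH_AMPLITUDE,
            baseline=BASELINE,
            noise_sd=NOISE_SD,
            regime_label="high_on_high_amp",
            on_prob_concentration=40.0,
            amplitude_cv=0.25,
        ),
        "low_on_high_amp": TelegraphParams(
            k_on=0.1,
            k_off=0.6,
            amplitude=HIGH_AMPLITUDE,
            baseline=BASELINE,
            noise_sd=NOISE_SD,
            regime_label="low_on_high_amp",
            on_prob_concentration=25.0,
            amplitude_cv=0.25,
        ),
    }


@dataclass(frozen=True)
class StageProfile:
    """One differentiation stage's share of the axis and its regime mixture."""

    stage: str
    position_range: tuple[float, float]
    regime_weights: tuple[float, float, float]  # basal, high_on_high_amp, low_on_high_amp
    params_per_regime: dict

    def __post_init__(self):
        w = np.asarray(self.regime_weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("regime weights must be non-negative and sum to 1")
        lo, hi = self.position_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("position_range must be a non-empty sub-interval of [0, 1]")


def default_stage_profiles() -> list[StageProfile]:
    """Six stages partitioning [0, 1] into sextiles with the default mixtures."""
    edges = np.linspace(0.0, 1.0, 7)
    return [
        StageProfile(
            stage=s,
            position_range=(float(edges[i]), float(edges[i + 1])),
            regime_weights=_REGIME_WEIGHTS[s],
            params_per_regime=_regime_params(s),
        )
        for i, s in enumerate(STAGE_LABELS)
    ]


def well_separated_profiles() -> list[StageProfile]:
    """Default stage profiles with within-regime amplitude variation removed.

    The three regimes then differ cleanly in amplitude (ratio 2.4) and ON
    fraction (sporadic ~0.14 vs continuous ~0.95), the separation regime used
    to measure how well the behaviour classifier recovers generating labels.
    """
    out = []
    for prof in default_stage_profiles():
        ppr = {
            name: replace(p, amplitude_cv=0.0) for name, p in prof.params_per_regime.items()
        }
        out.append(replace(prof, params_per_regime=ppr))
    return out


def simulate_markers(position: float, noise_cv: float = 0.2, seed=None, rng=None):
    """Raw CD71/Ter119 intensities for a cell at an axis position.

    The noiseless mean trajectory is exactly the staging module's canonical
    curve (CD71 rises early then declines late; Ter119 rises late), mapped
    back to raw arbitrary units.  Noise is multiplicative lognormal with the
    requested coefficient of variation and unit mean.
    """
    if not 0.0 <= position <= 1.0:
        raise ValueError("position must lie in [0, 1]")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed) if rng is None else rng
    pt = _CANONICAL_CURVE.point_at(position)
    cd71, ter119 = inverse_transform_markers(pt[0], pt[1])
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        factors = rng.lognormal(-(sigma**2) / 2, sigma, size=2)
        cd71, ter119 = cd71 * factors[0], ter119 * factors[1]
    return float(cd71), float(ter119)


_CANONICAL_CURVE = canonical_curve(P=20_001)  # generator-side copy, finer than staging's default


def cell_size_trend(position) -> np.ndarray:
    """Mean cross-sectional area (um^2) versus axis position.

    Erythroblasts shrink as they mature (~150 um^2 sections early, ~55 late);
    superimposed regular wiggles give the axis-alignment procedure a signal,
    standing in for the size fluctuations seen along real axes.
    """
    p = np.asarray(position, dtype=float)
    # quasi-periodic wiggle: two incommensurate components, so profile
    # alignment has a unique optimum (a pure sine would alias at +- period)
    return 150.0 - 90.0 * p + 12.0 * np.sin(3 * 2 * np.pi * p) + 7.0 * np.sin(
        np.sqrt(2) * 5 * np.pi * p + 1.0
    )


@dataclass(frozen=True)
class SyntheticCell:
    """Ground-truth bundle for one simulated cell."""

    cell_id: str
    stage: str
    true_regime: str
    true_position: float
    trace: IntensityTrace
    frame_occupancy: np.ndarray = field(repr=False)
    sample_states: np.ndarray = field(repr=False)
    marker_cd71: float = np.nan
    marker_ter119: float = np.nan
    cell_size: float = np.nan
    params: TelegraphParams = None
    stack: "RenderedStack | None" = None


def _cell_rng(master_seed: int, index: int):
    """Per-cell generator: SeedSequence(master) spawned at key (index,).

    A counter scheme, so cell i is reproducible regardless of how many cells
    are generated or in what order.
    """
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(index,)))


def _draw_cell_params(params: TelegraphParams, rng) -> TelegraphParams:
    out = params
    if params.on_prob_concentration is not None:
        c = params.on_prob_concentration
        total = params.k_on + params.k_off
        p = float(np.clip(rng.beta(c * params.p_on, c * (1 - params.p_on)), 1e-4, 1 - 1e-4))
        out = replace(out, k_on=total * p, k_off=total * (1 - p))
    if params.amplitude_cv > 0:
        s = np.sqrt(np.log1p(params.amplitude_cv**2))
        out = replace(out, amplitude=out.amplitude * float(rng.lognormal(-s * s / 2, s)))
    return out


def simulate_population(
    profiles=None,
    n_cells_per_stage=50,
    duration: float = 60.0,
    frame_interval: float = 2.5,
    seed: int = 0,
    marker_noise_cv: float = 0.2,
    size_noise_sd: float = 6.0,
    instantaneous: bool = False,
) -> list[SyntheticCell]:
    """Generate a staged population of synthetic cells.

    ``n_cells_per_stage`` may be a single count or one count per profile.
    Each cell draws its position uniformly within its stage's range, its
    regime from the stage's mixture weights, and its trace, markers and size
    from the per-cell generator derived from ``seed``.
    """
    profiles = default_stage_profiles() if profiles is None else list(profiles)
    counts = (
        [int(n_cells_per_stage)] * len(profiles)
        if np.isscalar(n_cells_per_stage)
        else [int(c) for c in n_cells_per_stage]
    )
    if len(counts) != len(profiles):
        raise ValueError("n_cells_per_stage must be scalar or one count per profile")
    if any(c < 0 for c in counts):
        raise ValueError("cell counts must be non-negative")
    cells = []
    index = 0
    for prof, n in zip(profiles, counts):
        for _ in range(n):
            rng = _cell_rng(seed, index)
            lo, hi = prof.position_range
            pos = float(rng.uniform(lo, hi))
            regime = REGIMES[int(rng.choice(3, p=np.asarray(prof.regime_weights, float)))]
            params = _draw_cell_params(prof.params_per_regime[regime], rng)
            cid = f"cell{index:05d}"
            sim = simulate_trace(
                params,
                duration=duration,
                frame_interval=frame_interval,
                rng=rng,
                cell_id=cid,
                instantaneous=instantaneous,
            )
            cd71, ter119 = simulate_markers(pos, noise_cv=marker_noise_cv, rng=rng)
            size = float(cell_size_trend(pos) + rng.normal(0.0, size_noise_sd))
            cells.append(
                SyntheticCell(
                    cell_id=cid,
                    stage=prof.stage,
                    true_regime=regime,
                    true_position=pos,
                    trace=sim.trace,
                    frame_occupancy=sim.frame_occupancy,
                    sample_states=sim.sample_states,
                    marker_cd71=cd71,
                    marker_ter119=ter119,
                    cell_size=size,
                    params=params,
                )
            )
            index += 1
    return cells


def population_truth_frame(cells) -> pd.DataFrame:
    """Ground-truth table (cell_id, stage, true_regime, true_position, markers, size)."""
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "stage": [c.stage for c in cells],
            "true_regime": [c.true_regime for c in cells],
            "true_position": [c.true_position for c in cells],
            "cd71": [c.marker_cd71 for c in cells],
            "ter119": [c.marker_ter119 for c in cells],
            "cell_size": [c.cell_size for c in cells],
        }
    )


# --- 3D stack rendering ----------------------------------------------------


@dataclass(frozen=True)
class StackSpec:
    """Geometry and photometry of a rendered cell stack.

    Shapes follow array order (z, y, x); voxel size is (x, y, z) in nm as in
    acquisition metadata.  Intensity levels: flat ``background`` outside the
    cell, a GFP-bright ``cytoplasm`` shell, and a GFP-depleted ``nucleus``
    (background <= nucleus < cytoplasm), the contrast that makes a
    pseudo-nuclear marker segmentable.  The spot is an isotropic-in-um
    Gaussian at ``spot_offset_um`` from the nuclear centre.
    """

    shape: tuple[int, int, int] = (30, 144, 144)
    voxel_size_nm: tuple[float, float, float] = (86.0, 86.0, 500.0)
    cell_radius_um: float = 5.0  # erythroblast-scale: ~10 um cell, ~7 um nucleus
    nuclear_radius_um: float = 3.5
    nuclear_offset_um: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (x, y, z)
    background: float = 100.0
    cytoplasm: float = 400.0
    nucleus: float = 150.0
    spot_amplitude: float = 800.0
    spot_sigma_um: float = 0.25
    spot_offset_um: tuple[float, float, float] = (1.5, 1.0, 0.0)  # from nuclear centre
    noise_sd: float = 0.0

    def __post_init__(self):
        if min(self.shape) < 1 or min(self.voxel_size_nm) <= 0:
            raise ValueError("shape and voxel sizes must be positive")
        if not self.background <= self.nucleus < self.cytoplasm:
            raise ValueError("levels must satisfy background <= nucleus < cytoplasm")
        off = np.linalg.norm(self.nuclear_offset_um)
        if off + self.nuclear_radius_um >= self.cell_radius_um:
            raise ValueError("nucleus must lie strictly inside the cell")
        if np.linalg.norm(self.spot_offset_um) >= self.nuclear_radius_um:
            raise ValueError("spot must lie inside the nucleus")


@dataclass(frozen=True)
class RenderedStack:
    stack: ImageStack
    cell_mask: np.ndarray = field(repr=False)
    nuclear_mask: np.ndarray = field(repr=False)
    spot_center_um: tuple[float, float, float]  # (x, y, z)
    spec: StackSpec = None


def _coordinate_grids_um(shape, voxel_size_nm):
    vx, vy, vz = (v / 1000.0 for v in voxel_size_nm)
    nz, ny, nx = shape
    z = np.arange(nz)[:, None, None] * vz
    y = np.arange(ny)[None, :, None] * vy
    x = np.arange(nx)[None, None, :] * vx
    return x, y, z


def render_stack(spec: StackSpec = StackSpec(), seed=None, rng=None) -> RenderedStack:
    """Render a 3D GFP stack with ground-truth masks and spot parameters.

    Physical coordinates are um from the centre of voxel (0, 0, 0).  The cell
    is centred in the field of view.  Noise is additive Gaussian (a practical
    approximation to shot noise at these levels), and voxel values are
    clipped at zero so the stack stays a non-negative intensity grid.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    x, y, z = _coordinate_grids_um(spec.shape, spec.voxel_size_nm)
    nz, ny, nx = spec.shape
    vx, vy, vz = (v / 1000.0 for v in spec.voxel_size_nm)
    center = np.array([(nx - 1) / 2 * vx, (ny - 1) / 2 * vy, (nz - 1) / 2 * vz])
    nuc_center = center + np.asarray(spec.nuclear_offset_um, dtype=float)
    d2_cell = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    d2_nuc = (x - nuc_center[0]) ** 2 + (y - nuc_center[1]) ** 2 + (z - nuc_center[2]) ** 2
    cell_mask = d2_cell <= spec.cell_radius_um**2
    nuclear_mask = d2_nuc <= spec.nuclear_radius_um**2
    nuclear_mask &= cell_mask  # geometry guarantees this; enforce for safety
    vox = np.full(spec.shape, spec.background, dtype=float)
    vox[cell_mask] = spec.cytoplasm
    vox[nuclear_mask] = spec.nucleus
    spot_center = nuc_center + np.asarray(spec.spot_offset_um, dtype=float)
    if spec.spot_amplitude > 0:
        d2_spot = (
            (x - spot_center[0]) ** 2 + (y - spot_center[1]) ** 2 + (z - spot_center[2]) ** 2
        )
        vox = vox + spec.spot_amplitude * np.exp(-d2_spot / (2 * spec.spot_sigma_um**2))
    if spec.noise_sd > 0:
        vox = np.clip(vox + rng.normal(0.0, spec.noise_sd, size=spec.shape), 0.0, None)
    return RenderedStack(
        stack=ImageStack(voxels=vox, voxel_size_nm=spec.voxel_size_nm, channel="GFP"),
        cell_mask=cell_mask,
        nuclear_mask=nuclear_mask,
        spot_center_um=tuple(float(c) for c in spot_center),
        spec=spec,
    )


def render_marker_stack(
    rendered: RenderedStack, mean_level: float, channel: str, noise_sd: float = 0.0, rng=None
) -> ImageStack:
    """A marker-channel stack: flat background plus ``mean_level`` inside the cell."""
    rng = np.random.default_rng() if rng is None else rng
    spec = rendered.spec
    vox = np.full(spec.shape, spec.background, dtype=float)
    vox[rendered.cell_mask] += mean_level
    if noise_sd > 0:
        vox = np.clip(vox + rng.normal(0.0, noise_sd, size=spec.shape), 0.0, None)
    return ImageStack(voxels=vox, voxel_size_nm=spec.voxel_size_nm, channel=channel)
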