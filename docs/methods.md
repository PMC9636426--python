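# Methods

This note documents the models, defaults and numerical choices behind
`burststage`, and what the synthetic tests do and do not establish about
real data.

## Burst metrics from intensity traces

A trace is the piecewise-linear interpolant of its samples (cell_id, time in
minutes, spot intensity in arbitrary units; background-corrected intensities
may be negative and are never floored — flooring would bias both the Fano
factor and output near zero).  ON intervals are the maximal intervals with
interpolant >= the ON threshold; crossing times are solved exactly on each
linear segment, so ON duration and burst sizes carry no grid error.  A
sample exactly at the threshold counts as ON: intervals are closed and the
threshold response is right-continuous.  Isolated touches (a single sample
at the threshold with both neighbours below) have zero measure and are
dropped, since a burst must have positive duration.

Burst size is the trapezoid area of (interpolant − threshold) over the
interval.  An interval touching either end of the imaging window is an
*incomplete* burst: excluded from duration/size distributions, but included
in the cell's transcriptional output (the sum of all interval areas).  The
ON fraction uses the total elapsed time of the trace as denominator.

Default ON threshold: 350 a.u., with a robustness harness that re-evaluates
stage rankings at thresholds 250–450 and counts complete bursts over a wide
sweep (default grid 0–1600 a.u. in steps of 100); the count peaks at an
interior threshold because very low thresholds never switch OFF and very
high ones never switch ON.

### Frame-interval selection

To choose an imaging rate, traces are decimated (every k-th sample),
linearly interpolated back onto the raw grid (held constant past the last
kept sample), and compared by RMSE over all raw points.  The comparison grid
is the raw grid — this choice penalises information loss at every observed
point; the recommended interval is the largest candidate whose median
per-cell RMSE fits a budget (smallest candidate plus a warning flag when
none does).

## Staging on a two-marker differentiation axis

Raw CD71/Ter119 intensities are compressed with `asinh(x / cofactor)`
(default cofactor 150 a.u.) — a one-parameter, invertible stand-in for the
biexponential/logicle display scale, with the same monotone compressive
behaviour.  The axis is defined by a family of polyline trajectories in
transformed space, each resampled to P = 10,000 points equally spaced in
cumulative arc length.  A cell's position is the arc-length fraction of the
Euclidean-nearest discretised point over all curves (first-minimum argmin:
ties resolve to the lowest curve index, then the lowest point index).
Positions bin into DS1–DS6 with half-open bins; default boundaries are equal
sextiles.  The shipped three-curve family (low/medium/high CD71 starts) and
the boundaries are package defaults, config-overridable — such trajectories
are defined empirically per experiment.

Two datasets' axes are aligned by their cell-size profiles: median size in
25 position bins, gap-interpolated and 3-point-median smoothed, then scanned
over integer-bin shifts for the maximal Pearson correlation (default maximum
shift 0.3, failure below correlation 0.5).  The default mapping is a global
shift (piecewise warping would be under-determined by a qualitative
procedure); the returned mapping is monotone.

## Variability

Fano factor = variance / mean of a cell's intensity samples, with the
population divisor n by default (the trace is the full observation, not a
sample of a longer stationary record; `ddof=1` is a switch).  Cells with
non-positive mean have an undefined Fano factor and are excluded from Fano
analyses with a logged count.  Stage-level statistics: percentile bootstrap
CIs for medians (default 10,000 resamples of size 31, so every stage is
resampled at the depth of the smallest group), OLS Fano-versus-mean slopes
per stage with slope ratios against the pooled slope, and two-sided
Mann-Whitney U tests (DS1 vs DS4 and DS4 vs DS6 by default) without
multiple-testing correction (a Benjamini-Hochberg option exists, off by
default).

A known divergence from real data: with occupancy-driven intensities,
trace variance falls as the promoter approaches saturation, so the
generator's within-stage Fano-mean slope can be negative at high-ON stages,
whereas measured data (where amplitude heterogeneity dominates) shows
positive slopes.  Slope-ratio comparisons remain meaningful; the sign of the
slope is not a property the generator tries to reproduce.

## Behaviour classification

Output versus ON duration is smoothed by robust LOWESS (local linear,
tricube weights, 3 bisquare reweighting iterations; span default 0.3,
exposed in config, with the inflection's stability across spans
{0.2, 0.3, 0.4} reported).  The inflection is the interior grid point
maximising the positive second difference of the lightly smoothed gradient;
a flat or uniformly sloped gradient raises a no-inflection error.  Boundary
grid points are excluded: their gradient estimates are one-sided.  Cells
above the inflection are High ON (ties are Low ON).

The basal expectation is a least-squares quadratic through the Low-ON
segment of the LOWESS grid, **anchored at the origin** (zero ON duration
produces exactly zero output).  The anchor matters numerically: a free
intercept absorbs smoothing noise at the short-duration boundary, and the
deviation score divides by ON duration, so an intercept error of c
contributes −c/d to the score — unbounded as d → 0, inflating the Low-ON
score SD and destroying the threshold separation.  The unconstrained fit is
available via `through_origin=False`.

Deviation score = (output − quadratic(duration)) / duration; silent cells
(duration 0) score 0 and are basal — a gene that never fires exhibits no
amplitude.  The high-amplitude threshold is the Low-ON score median + 1
standard deviation (plain SD over all Low-ON scores; one-sided upward, since
only high-amplitude excess is classified).  Final classes: basal (any ON
level), high-ON high-amplitude, low-ON high-amplitude.

## Image quantification

Segmentation is a two-step k-means on voxel intensities (k = 2, 10
restarts, fixed seeded initialisation, intensity as the only feature).  The
brighter cluster — after morphological closing, keeping the connected
component containing (or nearest) the marked centroid, and filling holes —
is the cell mask; free GFP-tagged coat protein fills the cytoplasm, so the
hole-fill recovers the full cell from its bright shell.  Within the cell
mask, the dimmer cluster's largest component (closed, hole-filled) is the
pseudo-nucleus.  Uniform inputs raise a segmentation error with cluster
diagnostics.

Spot intensity: mean over a 1 x 1 x 3 um axis-aligned ovoid at the spot,
minus the mean of a 3 x 3 x 3 um cuboid at the same z displaced 3 um in xy
toward (and past) the nuclear centroid, clipped to the nuclear mask.  Voxel
membership is by voxel-centre inclusion — bit-reproducible.  Voxel indices
are 0-based (z, y, x); physical coordinates are um from the centre of voxel
(0, 0, 0), reported (x, y, z).  Corrected intensities may be negative.

Spot detection (a documented stand-in for the external tracking software
used with such data): difference-of-Gaussians at the expected spot scale
(sigma 0.25 um against 3x that), brightest in-nucleus maximum accepted above
5 MAD-based robust SDs of the in-nucleus response; absence is a valid
outcome and callers reuse the last visible spot's coordinates.

Marker levels: mean inside the cell mask minus an inpainted background — the
masked region is repeatedly replaced by neighbourhood means (3-voxel uniform
filter) with outside voxels clamped to their observed values, until the
maximum change is < 1e-3 (cap 5000 iterations); the fixed point interpolates
the outside field harmonically, so linear gradients are recovered exactly.
Cell size: mask pixel count in the central z-slice (rounded z-centroid)
times pixel area — adequate for near-spherical erythroid cells.

## Synthetic generator

The generator defines the study conditions for every test.  Traces are
exact-event (Gillespie) two-state promoter simulations started from the
stationary distribution; the intensity at each 2.5-min sample over 60 min is
baseline + amplitude x (fraction of the preceding frame spent ON) + Gaussian
noise — frame-averaged occupancy mimics camera integration and produces the
intermediate intensities of real traces (an instantaneous mode is a switch;
the first sample, with no preceding frame, uses the instantaneous state).
No RNA dwell-time convolution is applied: amplitude differences stand in for
initiation-rate differences, since spot intensity, not RNA count, is the
measured quantity.

Default calibration (generator choices, not estimates of any dataset):
baseline 100 a.u., basal amplitude 500, high amplitude 1200 (ratio 2.4),
noise sd 60.  Three regimes: basal (stage-dependent ON probability
0.40/0.62/0.75/0.68/0.48/0.30 for DS1–DS6, total switching rate 0.8/min),
high-ON high-amplitude (k_on 2.0, k_off 0.1/min), and low-ON high-amplitude
(k_on 0.1, k_off 0.6/min).  Mixtures keep basal >= 72% everywhere, with
continuous high-amplitude bursting enriched at DS3-4 and sporadic bursting
at DS1-2 and DS5 — the qualitative rise-peak-fall of nascent transcription
across erythroid maturation.

Two within-regime heterogeneities make populations realistic rather than
degenerate: each cell draws its stationary ON probability from a Beta
distribution around the regime mean (concentration 2 for basal, 40/25 for
the high/low regimes; total switching rate preserved), because basal cells
span the whole ON-duration continuum in real populations and the Low-ON
basal expectation is only identifiable if they do; and each cell draws its
amplitude from a unit-mean lognormal (CV 0.25), because a population sharing
one exact plateau intensity is an artefact — it even produces a spurious
second mode in threshold sweeps at the common plateau level that
continuous-amplitude data cannot show.

Markers: the noiseless CD71/Ter119 trajectory at position p is exactly the
staging module's canonical curve at arc-length fraction p, mapped back to
raw units, with multiplicative unit-mean lognormal noise (default CV 0.2).
Cell size falls from ~150 to ~55 um^2 across the axis with a quasi-periodic
wiggle (two incommensurate sinusoids, amplitudes 12 and 7 um^2) — the
fluctuation signal the axis alignment uses; a single pure sinusoid would
make alignment ambiguous at shifts of one period.  Stacks: 30 z-slices of
144 x 144 pixels at 86 x 86 x 500 nm voxels; a 5-um-radius cell with a
3.5-um nucleus (erythroblast-like nuclear:cell ratio), levels
background/nucleus/cytoplasm = 100/150/400 a.u., an isotropic 0.25-um-sigma
Gaussian spot in the nucleus, additive Gaussian noise (a practical
approximation to shot noise at these levels) clipped at zero.

Seeding: one master seed; cell i uses `SeedSequence(master, spawn_key=(i,))`,
so populations are reproducible under any generation order.

### What the generator does not emulate

Photobleaching, optical PSF structure beyond a Gaussian spot, RNA
export/cytoplasmic foci, drift, mitotic/dead cells, or quantitative marker
and amplitude distributions of any real dataset (none are published at trace
level).  Tests passing on this generator show the *algorithms* are correct
and the designed structure is recoverable at realistic noise; they do not
certify performance on features the generator lacks.

## Problem sizes and tolerances

Tests and the acceptance script run at desk scale: 10,000 cells for
telegraph stationarity (tolerance 0.02 on the ON fraction), 500 cells for
staging recovery (Spearman >= 0.95 at marker CV 0.15; noiseless projection
error bounded by the 1/9,999 arc-length discretisation), 600 cells for
classifier recovery (>= 90% with well-separated regimes), 500 replications
for bootstrap coverage (93–97% band), and 1,800 cells (300 per stage) for
the threshold-robustness harness — the smallest size at which the designed
stage differences in median ON fraction clearly exceed median sampling
noise, so rank-order invariance is a property of the method rather than of a
lucky draw.  Interval algebra is compared to a dense-grid (1e-3 min) oracle
at 1e-6 relative tolerance after accounting for the oracle's own provable
quadrature error at crossings.
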