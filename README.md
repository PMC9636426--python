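# burststage

Analysis of transcriptional bursting across erythroid differentiation from
live-cell nascent-transcription traces.

Genes are transcribed in bursts: episodes in which a fluorescently tagged
nascent-RNA spot (e.g. a PP7/PCP-GFP-labelled globin locus) rises above an
ON threshold, separated by quiescent periods.  To ask how bursting changes
as cells differentiate, each cell must be placed on a differentiation axis
*at the microscope*: its CD71 and Ter119 surface-marker intensities are
transformed (asinh), projected onto the nearest point of a family of
marker-trajectory curves, and the arc-length fraction of that point (0 to 1)
is binned into six stages DS1-DS6 (proerythroblast through late
erythroblast).  Per cell, the spot-intensity trace y(t) is interpolated
linearly and summarised by:

- **ON fraction** — fraction of the imaging window with y(t) >= threshold
  (the live-cell analogue of the fixed-cell burst fraction);
- **burst duration / size** — per ON interval, its length and the area
  between y(t) and the threshold; only *complete* bursts (below threshold on
  both sides) enter duration/size distributions;
- **transcriptional output** — the summed area above threshold over the
  whole trace, incomplete bursts included;
- **Fano factor** — variance/mean of y(t), a noise-to-signal measure.

Bursting *behaviour* is classified from the ON-duration-versus-output plane:
a robust LOWESS curve shows a step-change (inflection) in gradient separating
near-continuously active "High ON" cells from "Low ON" cells; a quadratic
fitted to the Low-ON part of the curve extrapolates the output expected from
basal-amplitude bursting, and each cell's **basal amplitude deviation score**
(output residual per minute of ON time) is thresholded at the Low-ON median
+ 1 SD.  This yields three behaviours: basal amplitude, high-ON
high-amplitude, and low-ON high-amplitude (sporadic strong bursts).

The package also includes the supporting machinery: a telegraph-model
(two-state promoter) synthetic-data generator with ground truth, 3D-stack
quantification (two-step k-means cell/pseudo-nucleus segmentation, ovoid
spot measurement with nuclear background subtraction, iteratively smoothed
marker background, central-slice cell size), frame-interval selection by
subsampling RMSE, bootstrap median CIs, Mann-Whitney stage comparisons, and
an end-to-end pipeline with CLI.

## Worked example

```python
from burststage import simulate as sim, bursts as bm, classify as cl, staging as st
from burststage.variability import fano_factor

# a synthetic population with known ground truth: 50 cells per stage
cells = sim.simulate_population(n_cells_per_stage=50, seed=7)

# stage cells from their (noisy) marker intensities
staged = st.stage_cells([c.marker_cd71 for c in cells],
                        [c.marker_ter119 for c in cells],
                        cell_ids=[c.cell_id for c in cells])

# burst metrics at the 350 a.u. ON threshold
summ = bm.summaries_frame([c.trace for c in cells], threshold=350.0)
summ["stage"] = summ["cell_id"].map(staged.set_index("cell_id")["stage"])
print(summ.groupby("stage")[["on_fraction", "mean_intensity"]].median().round(3))

# behaviour classification
res = cl.classify_cells(summ[["cell_id", "on_duration", "output", "stage"]],
                        window_min=60.0)
print(f"inflection at {res.inflection_duration:.1f} min "
      f"({100 * res.inflection_fraction:.0f}% of the 60-min window)")
print(res.table["final_class"].value_counts().to_string())
```

prints

```
       on_fraction  mean_intensity
stage
DS1          0.315         274.552
DS2          0.642         404.532
DS3          0.855         464.145
DS4          0.893         502.346
DS5          0.434         327.485
DS6          0.311         277.816
inflection at 56.2 min (94% of the 60-min window)
final_class
BASAL               217
HIGH_ON_HIGH_AMP     47
LOW_ON_HIGH_AMP      36
```

Median ON fraction rises to a mid-differentiation peak (DS3-4) and falls at
the flanks — the generator's designed trajectory, recovered end to end from
noisy markers and noisy traces.  The inflection sits where cells are active
>90% of the window, and most cells burst with basal amplitude, with
continuous high-amplitude bursting concentrated mid-differentiation.

The same pipeline runs from the shell:

```sh
burststage run --seed 7 --outdir out/        # simulate + analyse + report
burststage bursts --traces traces.csv --threshold 350 --outdir out/
```

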