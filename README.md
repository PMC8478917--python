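# lamellikine

Quantification of cell motility and lamellipodial dynamics from microscopy
data, with seeded synthetic-data generators so every analysis stage is
testable against known ground truth.

Four analysis stages:

- **track_metrics** — interval-based migration statistics from cell-track
  tables: displacement sampling at a *usable time interval* δt (chosen so
  positional tracking error falls below 10% of the mean displacement), Mean
  Track Speed, Mean Track Persistence over windows Δt = TR·δt, mean
  persistence profile, mean square displacement, directionality ratio over
  time and direction autocorrelation.
- **edge_dynamics** — segmentation of single-channel time-lapse movies,
  signed edge-normal velocity mapped along the cell boundary, protrusion
  speed in a 60° cone about the migration direction, its standard deviation
  (stability), the longest uninterrupted protruding arc, protrusion length
  distributions, and curved-ROI morphometrics (centerline length, width,
  area and intensity ratios).
- **flow_piv** — particle image velocimetry of intracellular actin flow by
  zero-normalised cross-correlation template matching (source box 0.3 µm,
  search box 0.5 µm, grid 0.2 µm, correlation threshold 0.5, optional
  sub-pixel Gaussian peak refinement), dense interpolation by normalised
  convolution with truncated Gaussian kernels (spatial 3 µm / σ 0.5 µm,
  temporal 15 s / σ 6 s), mean flow speed and the F-actin assembly rate
  (|flow| + |protrusion|).
- **flim_fret** — per-pixel mono-exponential lifetime fitting of TCSPC
  photon histograms (Levenberg–Marquardt tail fit with Poisson-motivated
  weights), FRET efficiency maps via E = 1 − τ_DA/τ_D, histograms and
  photon-weighted per-cell mean efficiencies.

The **synthetic_data** module generates correlated-random-walk tracks
(lognormal speeds, von Mises turning angles, additive positional noise),
textured movies with a prescribed uniform retrograde flow and edge
protrusion, sector-protrusion mask movies, and Poisson TCSPC stacks — each
with a `GroundTruth` record attached. The **pipeline** module orchestrates
simulate → analyse → summarise runs with per-stage seed splitting and full
provenance in the output tables.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(parameter recovery, exact analytic values, determinism).

## CLI

```sh
# generate synthetic data with a ground-truth sidecar
lamellikine simulate --what tracks --out sim --seed 1

# per-cell speed/persistence from a tracking CSV (columns: track_id, frame, x_px, y_px)
lamellikine tracks --in tracks.csv --frame-interval 5 --pixel-size 0.65 \
    --delta-t 15 --tr 4 --alpha-mode raw --out stats.csv --profile --msd --autocorr

# edge-velocity profiling and lamellipodium metrics
lamellikine edge --in movie.tif --pixel-size 0.1 --frame-interval 5 \
    --cone 60 --vmin 0 --out edge_out

# retrograde-flow PIV on a masked movie
lamellikine flow --in seg.tif --mask masks.tif --pixel-size 0.05 \
    --frame-interval 3.22 --out flow_out

# per-pixel lifetime fitting and FRET efficiency
lamellikine flim --in tcspc.tif --meta tcspc_meta.json --tau-donor 4.0 --out flim_out

# end-to-end demo on synthetic data
lamellikine run --demo --out demo_run --seed 1
```

Fiji Manual Tracking exports (1-based slices, extra index column) are
accepted through `track_metrics.read_fiji_manual_tracking`.

## Conventions

- Tracks are in µm and minutes after ingestion; pixel/frame conversion
  happens only in the reader.
- Displacement intervals and persistence windows are non-overlapping,
  anchored at the first frame; trailing remainders are discarded.
- Edge velocity is the signed distance from a boundary point to the next
  frame's boundary (negative inside the next mask), so protrusion is
  positive; the last frame carries no velocity.
- All generators are bit-deterministic under their seed; pipeline stages
  split the master seed by hashing (seed, stage name).
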