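# calfluor

Calcium fluorometry for low-cost time-lapse fluorescence microscopy.

Portable incubator microscopes built from consumer digital-microscope parts
can record Fluo-4-loaded cells for hours at 8-bit grayscale, either slowly
(1 frame / 10 min over 10 h) to follow drift and cell death, or fast (1 Hz
for 150-s sessions every 2 h) to follow network activity in neuronal
cultures. `calfluor` is the analysis side of such a system: it turns those
movies into per-cell calcium traces, influx/efflux events, cell-death
timings, and functional-connectivity maps — and ships a synthetic movie
generator with full ground truth so every stage is testable without any
recording.

## What it computes

Given a movie of frames `F_pixel` and segmented cell-body ROIs, per ROI of
`n` pixels:

- mean intensity **F̄(t) = Σᵢ F_pixel,i / n**, and a per-frame background
  trace **F_Bkg(t)** over a mask away from all cells;
- background-normalized **F\*(t) = F̄(t) / F_Bkg(t)** (slow photobleaching
  cancels in the ratio) and relative fluorescence
  **F_rel(t) = (F̄ − F_Bkg) / F_max**, with F_max the global trace maximum;
- the derivative **ΔF\*/Δt** (backward difference, Δt = frame period),
  thresholded by a *double threshold*: a static cutoff (±0.05 per frame)
  combined with a varying cutoff (±5 × the derivative spread). Excursions
  above the positive threshold are calcium **influx** events; below the
  negative threshold, **efflux** events;
- **ΔT cell-death analysis**: ROIs showing exactly one influx followed by
  exactly one efflux are treated as dying cells and the delay
  ΔT = t(efflux) − t(influx) is tabulated and histogrammed;
- **connectivity maps**: pairwise synchrony between influx spike trains via
  the Sørensen-Dice coefficient, Dice(a,b) = 2|a∩b| / (|a|+|b|); ROI pairs
  with Dice ≥ θ (default 0.5) are linked in a spatial graph, summarized per
  session as the number of active cells, edge count, and edges per active
  cell;
- **image-quality characterization**: 43 × 43-pixel patches around bright
  objects compared pairwise by SNR, PSNR, MAE, RMSE, within one image or
  randomized across microscopes.

## Worked example

Run the full pipeline on a simulated 1-Hz session (30 cells, 150 frames,
shared network events joined with probability 0.6, realistic shot + read
noise):

```bash
calfluor run --preset fast_session_150s --seed 7 --out demo_run
```

prints the per-stage counts

```
{
 "n_active": 23,
 "n_deaths": 5,
 "n_edges": 45,
 "n_events": 87,
 "n_frames": 150,
 "n_influx": 53,
 "n_rois": 30
}
```

meaning: 30 cell bodies segmented, 87 supra-threshold events of which 53
are influxes, 23 ROIs active (≥ 1 influx), and 45 ROI pairs synchronous
enough (Dice ≥ 0.5) to be linked in the connectivity map — about 1.96
connections per active cell (`metrics.csv`). The run directory also holds
`traces.csv` (per ROI × frame: F̄, F_Bkg, F*, F_rel, ΔF*/Δt), `events.csv`,
the binary influx `raster.csv`, the graph as `graph.graphml` + `edges.csv`,
the simulated `movie.tif` with its ground truth, and quick-look plots.
(`death.csv` lists single-spike influx→efflux ROIs; over a 150-s session
these are spurious short-ΔT pairs — the analysis is meaningful on the
`long_term_10h` preset, where dying cells show a large influx plateau and a
terminal efflux hours later.)

The same stages are available as a library:

```python
from calfluor import preset, simulate, segment_cells, compute_traces
from calfluor import detect_events, build_raster, dice_matrix

movie, truth = simulate(preset("fast_session_150s").replace(seed=7))
rois = segment_cells(movie)
traces = compute_traces(movie, rois)
events = detect_events(traces.deriv, frame_period_s=movie.frame_period_s)
raster = build_raster(events, rois.n_rois, movie.n_frames)
dice = dice_matrix(raster)
```

## Layout

- `calfluor.simulate` — synthetic movies + ground truth, regime presets
- `calfluor.io` — TIFF/PNG movie I/O, RGB→8-bit reduction, CSV/GraphML
- `calfluor.quality` — patch extraction and SNR/PSNR/MAE/RMSE reports
- `calfluor.segment` — max-projection Otsu cell-body segmentation
- `calfluor.fluorometry` — F̄, F_Bkg, F*, F_rel, ΔF*/Δt traces
- `calfluor.events` — double-threshold detection, rasters, ΔT analysis
- `calfluor.network` — Dice matrices, connectivity graphs, session metrics
- `calfluor.pipeline` / `calfluor.cli` — end-to-end runs, `calfluor` CLI

See `docs/methods.md` for the model, parameter choices, and limitations.
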