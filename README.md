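# edgedyn

Quantification of cell-edge dynamics from calibrated two-channel time-lapse
fluorescence movies of single migrating cells, plus adhesion-site morphometry
and cell-motility metrics, with a synthetic-movie generator that plants
ground truth for every stage.

The pipeline:

1. **Segmentation & boundary tracking** — per-frame cell masks (automatic
   between-class-variance threshold, pluggable), sub-pixel closed boundaries
   with outward normals, division into ~10 μm arclength sectors anchored at a
   reproducible reference point, and frame-to-frame sector correspondence by
   normal-ray casting.
2. **Velocity heatmap** — per sector and frame pair, the displacement
   projected on the outward normal (V = d · n), normalized to [−1, 1]
   (protrusion +1, quiescence 0, retraction −1), rendered as a sector × time
   heatmap.
3. **Edge-band colocalization** — a 2 μm-deep band inside the boundary,
   partitioned into the same sectors; per region and frame the Pearson-type
   correlation of background-subtracted two-channel pixel intensities,
   rendered as a heatmap (0 = low, 1 = high).
4. **Coupling map** — the elementwise product C = V × coloc with symmetric
   min–max normalization across all cells in an analysis set (+1 coupled
   protrusion/high colocalization, −1 coupled retraction/high colocalization).
5. **Event extraction** — connected above-threshold heatmap regions (with
   circular wraparound in the sector axis) with area, duration, major-axis
   angle from the time axis; events steeper than 10° (strict) are classified
   as traveling waves. Summaries: mean duration, events/cell/minute, mean
   angle, percent traveling waves.
6. **Adhesion sites** — puncta detection inside a lamellipodium ROI
   (smoothing, automatic threshold, 0.1 μm² size exclusion); area,
   longest-axis length, and centroid distance to the leading-edge membrane.
7. **Motility** — meandering index (displacement/path length), scratch-wound
   percent area closed, and cytoplasmic:nuclear intensity ratio.

The `synthetic` module renders star-convex cells whose boundary moves under
configurable protrusion/retraction pulses (with lateral drift to plant
traveling waves), imposes a target edge-band channel correlation through a
shared latent field (including localized high-correlation patches), and
emits exact ground-truth tables — so every operator is testable without
external data.

## CLI

```bash
# synthetic movie with ground truth
edgedyn simulate --config sim.yaml --out-dir out/sim --seed 1

# full pipeline: masks, boundaries, three heatmaps, events, summaries, manifest
edgedyn all --movie out/sim/movie.tif --pixel-size 0.2 --frame-interval 5 \
    --out-dir out/run

# subsets
edgedyn dynamics --movie movie.tif --pixel-size 0.2 --frame-interval 5 --out-dir out/v
edgedyn coloc    --movie movie.tif --pixel-size 0.2 --frame-interval 5 --out-dir out/c
edgedyn coupling --movie movie.tif --pixel-size 0.2 --frame-interval 5 --out-dir out/cp

# adhesion morphometry (ROI/edge as x_um,y_um CSV point lists)
edgedyn adhesion --frame frame.tif --roi roi.csv --edge edge.csv --pixel-size 0.2 \
    --out-dir out/adh

# motility metrics
edgedyn motility --tracks tracks.csv --wound wound.csv --out-dir out/mot
edgedyn cnratio --frame f.tif --nucleus n.tif --cell c.tif
```

Movies are multi-page TIFF (axes T×C×Y×X, ImageJ-compatible); tables are CSV
with unit-suffixed column names and a `# config_hash=...` provenance line;
heatmaps are exported as CSV plus rendered PNGs (velocity: red/green/blue =
protrusion/quiescence/retraction; colocalization: blue→red; coupling:
five-color blue/cyan/green/orange/red). Every run writes `manifest.json`
with the config, its hash, library versions, and stage outputs.

## Layout

```
src/edgedyn/
  config.py          # SimConfig / PipelineConfig dataclasses, YAML I/O, hashing
  synthetic.py       # movie/adhesion/track/wound generators + ground truth
  segmentation.py    # masks, boundaries, sectors, sector tracking
  dynamics.py        # velocity heatmap, event extraction, summaries
  colocalization.py  # edge band, region correlation, coloc heatmap
  coupling.py        # V x coloc map, cross-cell normalization
  adhesion.py        # puncta detection and morphometry
  motility.py        # meandering index, wound closure, C:N ratio
  pipeline.py        # end-to-end driver + manifest
  io.py, cli.py      # TIFF/CSV/PNG I/O and the click CLI
```
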