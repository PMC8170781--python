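# woundscope

Cell-scale and population-scale analysis of in vitro wound-healing
(scratch/migration) assays: two confluent cell monolayers separated by a
cell-free gap close the wound by migration and proliferation, imaged by
time-lapse microscopy.  `woundscope` turns such an image sequence into
the quantities the assay is run for — per-column cell density, per-cell
velocities, the reconstructed leading edge of each monolayer, its
protrusion length and spatially averaged position, and the gap-closure
time course — and ships a synthetic-scene generator with complete ground
truth so every stage is testable without microscope data.

## What is inside

**Segmentation.** Two interchangeable cell detectors: an adaptive
local-mean threshold baseline (foreground iff
`I(x) > μ_w(x) · 2(1 − s)` over a 161 × 121 px window with sensitivity
s, plus hole filling and minimum-area cleanup) and a compact U-net
(3 encoder/decoder stages, skip concatenation, softmax over
background / cell / border classes) trained with the Tversky loss

    TI_c = (TP_c + ε) / (TP_c + α·FP_c + β·FN_c + ε),   L = mean_c (1 − TI_c)

with α = 0.3, β = 0.7 (α = β = 0.5 reduces to soft Dice).  The border
class keeps touching cells apart, so connected components of the cell
class are individual cells.  A 2-class variant of the same network
segments monolayer vs gap directly.  The network, its backward passes
and Adam are implemented in numpy and run on a plain CPU.

**Cell scale.** Centroid tracking by globally greedy nearest-neighbour
linking bounded by a maximum motion radius R (default 25 px ≙ 0.14 mm/h
at 1.4 µm/px and 15 min frames); 50-column profiles of density
(cells/mm²) and column-averaged speed (mm/h); and a two-pass
cross-correlation cell image velocimetry (CIV) baseline with 32–64 px
interrogation areas, 50 % overlap, Gaussian sub-pixel peak fit and
peak-ratio + median-test validation.

**Population scale.** Leading-edge reconstruction from segmented cells
(dilate by a 15 px disk, keep the two largest areas — which discards
debris — erode back), from a direct monolayer/gap mask, or by the
classical Canny route; edge protrusion length, spatially averaged edge
position, gap width and closure time; relative-error series against a
reference; IoU, boundary-F1 and paired-t count comparison for
validation.

**Synthetic assays.** `simulate_scene` renders textured elliptical
cells on a static substrate, with directed edge migration (optionally
asymmetric between the upstream and downstream front), an isotropic
random walk, optional division and shape deformation, and emits exact
ground truth: per-cell centroids/velocities, per-pixel label maps,
3-class and 2-class masks, and true edge positions.

## Worked example

```python
import numpy as np
import woundscope as ws

# a 1.4 x 0.54 mm field of view, 500 um gap, 6 frames at 15 min
cfg = ws.SceneConfig(n_frames=6, seed=3, v_edge_mm_h=0.03, v_inner_mm_h=0.02)
seq, gt = ws.simulate_scene(cfg)

# segment frame 0 with the adaptive threshold and profile the density
seg = ws.AdaptiveSegmenter(sensitivity=0.6).fit()
dets = [seg.detect(seq[t], t) for t in range(seq.n_frames)]
density = ws.density_profile(dets[0], cfg.width_px, cfg.height_px, cfg.pixel_size_um)
print(f"{len(dets[0])} cells detected (ground truth {gt.n_cells(0)})")
print(f"peak column density {np.nanmax(density.values):.0f} cells/mm^2")

# track and measure speeds
tracks = ws.track_sequence(dets, R_px=25, pixel_size_um=cfg.pixel_size_um, dt_min=cfg.dt_min)
speeds = [s for tr in tracks for s in tr.speeds_mm_h]
print(f"{len(tracks)} tracks, mean speed {np.mean(speeds):.3f} mm/h")

# leading edges from the ground-truth monolayer masks
pairs = []
for t in range(seq.n_frames):
    left, right, _ = ws.edge_from_idsd(gt.monolayer_masks[t] > 0, cfg.pixel_size_um, frame=t)
    pairs.append((left, right))
series = ws.edge_timeseries(pairs, cfg.dt_min)
print(f"gap width {series.gap_width_mm[0]:.3f} -> {series.gap_width_mm[-1]:.3f} mm over {(seq.n_frames-1)*cfg.dt_min:.0f} min")
```

prints

```
257 cells detected (ground truth 251)
peak column density 779 cells/mm^2
345 tracks, mean speed 0.029 mm/h
gap width 0.527 -> 0.476 mm over 75 min
```

The detected count lands within a few percent of the ground truth; the
tracked mean speed sits between the configured interior (0.02 mm/h)
and edge (0.03 mm/h) speeds, nudged upward by segmentation jitter in
the centroids; and the ~0.5 mm gap narrows as both fronts advance at
0.03 mm/h over 1.25 h.

The same workflow is scriptable from the shell:

```bash
woundscope simulate --out scene --frames 6 --seed 3
woundscope segment --input scene/frames.tif --method adaptive --out seg
woundscope track --detections seg/detections.csv --radius 25 --out tracks.csv
woundscope report --config pipeline.yaml     # full configured run
```

Training a U-net segmenter and using it end to end:

```bash
woundscope train --labels scene --out model.npz --epochs 8
woundscope segment --input scene/frames.tif --method icd --weights model.npz --out seg_icd
```

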