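# Methods

`woundscope` quantifies in vitro wound-healing (scratch) assays at two
scales: individual cells (density, per-cell velocity) and the monolayer
as an entity (leading-edge position, protrusion, gap closure).  This
note records the models, the parameter choices, and the numerical
decisions, together with what the synthetic validation can and cannot
show.

## The synthetic assay

No public live-cell dataset accompanies the workflow this package
implements, so every quantitative claim is validated on simulated
scenes with exact ground truth (`woundscope.synthgen`).  A scene is two
confluent cell monolayers separated by a vertical cell-free gap
(default 500 µm), imaged every `dt_min` = 15 min at `pixel_size_um` =
1.4 µm/px.  The pixel size is chosen so that the published
correspondence between the maximum linking radius and the maximum
linkable speed holds exactly: 25–30 px per 15 min ≙ 0.14–0.17 mm/h.

Cells are ellipses (mean radius 18 µm, s.d. 3 µm, axis ratio drawn in
[0.87, 1.07]) placed by dart throwing with a minimum separation of 1.9
mean radii at a default density of 600 cells/mm², a value typical of a
confluent endothelial monolayer.  Each cell carries

* a private value-noise texture sampled in cell-local coordinates, so
  the texture translates rigidly with the cell (image velocimetry sees
  genuine cell motion, not a static pattern);
* a radial intensity profile `peak · exp(-2.2 ρ²)` — bright cell body,
  dim rim — so neighbouring cells remain visually separated the way
  phase images of endothelial sheets are;
* pixel ownership by normalised ellipse distance, which makes the
  per-pixel cell-id map unambiguous even for slightly overlapping
  cells.

The background holds a **static substrate texture** (smooth Gaussian
field, amplitude 0.02 around a base level of 0.1).  This field does not
move between frames.  It matters for one specific reason: correlation
velocimetry locks onto any static grey-value signal in an interrogation
area, which is exactly the mechanism by which CIV underestimates true
cell speeds; without a substrate the simulated images would be
unrealistically favourable to CIV.

Kinematics: every cell's step is a directed component toward the gap
centre plus an isotropic Gaussian random walk.  Cells within 2.2 mean
radii of the gap-facing front ("border" cells) receive the full
directed edge speed `v_edge_mm_h` (side-specific:
`v_edge · (1 ± asymmetry)` for the upstream/downstream front); cells
behind the front receive the same drift attenuated by
`exp(-depth / 4 r̄)`, which lets the sheet advance without tearing.
The random-walk component σ is calibrated so the **mean** step
magnitude equals `v_inner_mm_h · dt` (a 2-D Gaussian step has Rayleigh
magnitude with mean σ√(π/2)); column-averaged tracked speed is then an
unbiased estimate of `v_inner_mm_h` wherever the drift vanishes.
Cells reflect off the image borders (a clamp would pile them up at the
walls and truncate their steps); note that confinement genuinely lowers
the mean displacement speed in the border columns, which is visible in
the ground-truth velocities as well.  Optional per-frame ellipse-axis
jitter (`deformation`) and stochastic division (`division_rate_per_h`,
daughters placed one diameter away) produce the
shape-change-plus-proliferation conditions under which velocimetry and
tracking are compared.

Ground truth per frame: cell records (id, rendered-region centroid,
area, forward-difference velocity of the continuous centre), the
cell-id label map, a 3-class map (background / cell interior / border
ring of configurable width, the ring being each cell's pixels removed
by erosion with a disk), a 2-class monolayer/gap mask (union of cells
closed with a mean-radius disk, border-padded so image-edge cells are
not eroded), and the true per-row edge positions.  Centroids are
recorded from the rendered regions so they agree with the label maps to
machine precision; velocities come from the continuous kinematics so
they are exact.

What the generator does **not** emulate: phase-contrast optics (halos,
shade-off), cell crawling morphology (lamellipodia), mitotic rounding,
apoptosis, debris drift, focus drift, or temporally correlated noise.
Passing tests therefore demonstrate the correctness and the relative
behaviour of the algorithms under controlled conditions, not their
absolute accuracy on real microscope data.

## Segmentation

**Adaptive local-mean threshold** (`segment_adaptive`): foreground iff
`value > local_mean · 2(1 − s)` over a 161 × 121 px reflected-border
window (mirrored comparison for dark cells), hole filling, then
removal of components below 50 px² (≈ 100 µm², well below a plausible
cell).  At sensitivity s = 0.5 the rule reduces to "above the local
mean" and foreground grows monotonically with s.  A structural
consequence worth stating: for s > 0.5 the threshold sits *below* the
local mean, so any flat region larger than the window — in particular
a wide cell-free gap — eventually fires.  With the default window
(161 px ≈ 225 µm) the method counts accurately when the scratch is
narrower than the window (the local mean stays propped up by cells on
both sides) and produces spurious gap detections when it is wider,
which is precisely the failure mode reported for threshold methods on
distorted images.  The count-accuracy test therefore uses a 150 µm
scratch; the noise-robustness comparison deliberately uses a 500 µm
one.

**U-net** (`woundscope.unet`): a compact encoder/decoder written
directly in numpy (forward and backward passes, Adam), since the
package targets CPU-only deployments.  Default architecture: 3 stages
of two 3 × 3 same-padded conv+ReLU blocks with 2 × 2 max pooling,
channel widths doubling from `base_features` (32 by default; the
validation suite trains a `base_features=8` variant, which is
sufficient for the synthetic contrast), a bridge with dropout 0.5, and
decoder stages of learned 2 × 2 stride-2 transposed convolutions with
skip concatenation; a 1 × 1 convolution and softmax produce per-pixel
class probabilities.  Arbitrary frame sizes are handled by
reflect-padding to the next multiple of 2^stages and cropping back.

Training minimises the **Tversky loss**: per class,
`1 − (TP + ε) / (TP + α FP + β FN + ε)` on probability-weighted (soft)
counts pooled over the batch, averaged over classes; α = 0.3, β = 0.7
weight missed cell pixels more heavily than spurious ones, and
α = β = 0.5 recovers soft Dice exactly (a property test pins this to
1e-9).  Whether the original averaged over classes or used the cell
class only is not documented; the class mean is implemented and the
single-class case is reachable by configuration.  Optimisation: Adam,
lr 0.001 decayed ×0.9 per epoch, mini-batches of 30, reshuffled every
epoch; per-image min-max normalisation to [0, 1].  Augmentation
(rotation ±180°, skew ±10°, translation ±10 %, brightness ±20 %;
geometric transforms nearest-neighbour on labels) is available and
off by default in the validation runs, which instead draw patches from
many independent scenes — more diverse than warped copies of few
scenes, at the same cost.  Training data for the validation model:
208 labelled 128 × 128 patches from 13 scenes, half of them distorted
with variance-0.01 Gaussian noise so the network learns to ignore the
distortion it is later tested under; 8 epochs.

iCD postprocessing: 3 × 3 median filter on the label map, border class
to background, cell class binarised, 8-connected components,
sub-minimal components dropped — which removes small artifacts as a
side effect.

## Cell-scale analytics

**Tracking**: globally greedy nearest-neighbour linking.  All
candidate pairs within the maximum motion radius R are sorted by
(distance, previous id, next id) and accepted when both endpoints are
free; this is one-to-one by construction (two cells cannot claim the
same successor; plain per-cell nearest-neighbour can).  Tracks
terminate at their first missed link — no gap closing, matching
strictly frame-to-frame linking.  R defaults to 25 px; per-step speed
is `distance · pixel_size / dt`.  Kinematic position prediction is
deliberately absent: cell motion is not smooth enough between frames
for it to help.

**Profiles**: the image is split into 50 equal columns perpendicular
to the gap (half-open bins, last closed).  Density = count of centroid
per column / column area (cells/mm²; a counts-per-mm-width variant is
exposed since both normalisations appear in practice).  Velocity =
column mean of per-step speed *magnitudes* assigned to the step's
start centroid; columns without samples are flagged undefined rather
than zero.

**CIV** (`civ_field`): two-pass normalised cross-correlation
velocimetry.  Coarse pass at 64 × 64 px interrogation areas on a 50 %
overlap grid predicts integer shifts for the final 32 × 32 px pass;
NCC is evaluated against every aligned window of a search region
(top-left convention — no centre-parity ambiguity), with a 3-point
Gaussian sub-pixel fit per axis.  Validity: correlation peak ratio
(highest / second-highest outside an exclusion zone of IA/8, wide
because cell-image correlation peaks are several pixels across) must
exceed 1.5, followed by a normalised-median test against the 8
neighbouring vectors (threshold 2.0, ε = 0.1 px) — the standard
universal outlier detection, needed because a plausible-looking false
peak appears wherever the displaced content has left the frame.

## Population-scale analytics

Three routes to a monolayer/gap view (`popscale`): from segmented
cells (dilate every cell with a disk of radius 15 px so boundaries
overlap, keep the **two largest** 8-connected areas, erode back with
the same disk treating the image border as foreground), directly from
a 2-class monolayer mask (two-largest rule only), or by the Canny
chain (edge map at σ = 1, dilation 1–20 px, small-component removal,
erosion).  The two-largest rule is what makes the cell route ignore
debris; the Canny route has no cell-level information to do so, and
any surviving foreground facing the gap counts toward its edge —
reproducing the fraying of gradient-based edges.

The gap is the largest background component 4-adjacent to both
monolayers; the **leading edge** of a monolayer is its pixels
4-adjacent to the gap, walked into ordered 8-connected chains
(greedy, 4-neighbour steps preferred, topmost-leftmost start).

Edge metrics.  The spatially averaged edge position is the mean x of
the raw edge pixels.  The protrusion length is the summed Euclidean
step length of the chain after smoothing the chain coordinates with a
7-point moving average (endpoints kept raw), plus one pixel for the
half-pixel extension of each endpoint to the image border.  The
smoothing is deliberate: the raw 1/√2 Freeman chain length
overestimates the length of a digitised smooth curve by up to ~11 %
(staircase excess, worst near slope ½), while the smoothed chain is
accurate to a fraction of a percent on a sinusoid of amplitude 20 px
and leaves straight edges exact — an H-row vertical edge measures
exactly H · pixel_size.  Gap width = mean_x(right) − mean_x(left);
closure is the first frame at which no two separated monolayers exist
(or the gap width reaches zero).

## Evaluation

IoU per class (empty-vs-empty defined as 1.0, preventing spurious
zeros on background-only tiles), boundary F1 with a Euclidean match
tolerance defaulting to 0.75 % of the image diagonal (computed with
distance transforms), paired two-sided t-test for per-frame count
comparison (the test is undefined for < 2 frames or constant
differences and flagged as such), and elementwise relative error with
zero references flagged NaN and excluded from means.

## Validation problem sizes

The automated checks run at deliberately compact sizes: scenes of
1024 × 384 px (≈ 1.4 × 0.54 mm) with ~250–350 cells; 80 frames for
column-wise speed recovery (≥ 500 tracked steps per assessed column,
so the sampling error of the Rayleigh-distributed step magnitudes
stays well inside the 10 % band; the two image-border columns are
excluded because wall reflection lowers the true displacement speed
there); 6-frame scenes for the
velocimetry-vs-tracking comparison; 208 training patches and 8 epochs
for the segmentation network.  The mini network reaches a held-out
cell-class IoU of ~0.84 on synthetic frames; published values on real
endothelial images (~0.82) are of the same order but not comparable —
real data are harder in texture and easier in training volume.

## Known limitations

* The numpy U-net is single-threaded BLAS-bound; it is meant for
  small models and patches, not for GPU-scale training.
* The edge tracer assumes an approximately function-like edge per
  monolayer; strongly folded fronts (overhangs enclosing background)
  would be traced as multiple segments.
* Track identity is greedy and radius-bound; dense fast motion
  (steps approaching the inter-cell spacing) will swap identities,
  as any nearest-neighbour linker does.
* The CIV implementation is a basic two-pass NCC scheme; it matches
  the published interrogation-area sizes and overlap but is not the
  commercial adaptive-correlation algorithm used alongside the
  original assays.
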