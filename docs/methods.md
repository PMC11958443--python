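# Methods

`leyes` generates abstract synthetic eye images for training eye-feature
localization models. The premise: a network that localizes pupils and
corneal reflections (CRs) only needs to find dark or bright blob-shaped
structures with the right luminance relations — it does not need
photorealistic eyes. Abandoning photorealism makes image generation cheap
enough to synthesize every training batch on the fly, so no image is ever
reused and the training distribution is the generator itself.

## Feature model

Blob features (pupil, CRs, spurious reflections) are anisotropic 2D
Gaussians

    G(x, y) = A · exp(−a·dx² − b·dx·dy − c·dy²)

with `dx = x − x_c`, `dy = y − y_c`, and quadratic-form coefficients derived
from the orientation θ and the per-axis spreads σ_minor, σ_major. The
spreads are parameterized by the desired *luminance-plateau* radii:

    σ = r / sqrt(2 · ln A)

so the field equals exactly 1 at distance r along each principal axis
irrespective of the amplitude A. Clipping the field at 1 yields a plateau
of constant luminance with fixed radius; A only controls the steepness of
the feature's edge (A slightly above 1 gives a diffuse blob, A in the tens
of thousands a near-binary disk). The cross coefficient is
`sin(2θ)·(1/(2σ_minor²) − 1/(2σ_major²))`, the unique choice for which the
quadratic form is an exact rotation; the half-size variant that appears
when the cross term is written as `2b·dx·dy` would break the plateau
identity for rotated features.

### Coordinate convention

0-based pixel indices; a pixel samples its center at integer coordinates;
x increases rightward, y downward; θ is measured from +x toward +y. All
labels use this frame, with continuous sub-pixel centers.

## Compositing

1. The background field is evaluated (uniform, split-line, linear gradient
   across the canvas diagonal, or sclera + layered iris).
2. Layers are applied in order. Dark features and soft-edged shapes blend
   the running image toward their luminance L with coefficient
   c = min(G, 1): `image ← image − (image − L)·c`, so the plateau renders
   at exactly L no matter what lies beneath. Bright features apply
   `image ← max(image, L·c)`.
3. i.i.d. Gaussian pixel noise N(0, σ_n²) is added on the 8-bit scale.
4. The image is clipped to [0, 255], scaled to [0, 1], and discretized to
   256 levels with round-half-away-from-zero — an explicit rule so renders
   are bit-exact and testable.

Rendering is a pure function of the scene description and an explicit noise
seed; all sampled quantities (feature parameters, collarette vertex jitter)
are frozen into the scene before rendering. Each generated image draws
from its own counter-indexed random substream, so dataset content is
independent of generation order and parallelism.

Soft-edged ellipses (the iris) blend with a raised-cosine coefficient
`(1 + cos(π·t))/2` across a band that extends *outward* from the ellipse
boundary by the edge width, parameterized along the ray from the center
(the inward/outward choice is a fixed convention). The collarette is a
polygon of 13–24 vertices at jittered radii, smoothed by a periodic cubic
spline sampled at five times the vertex count, filled with the same
raised-cosine edge via a Euclidean distance transform.

## Pipelines

Five generator families, each with a broad first-stage and a narrowed
second-stage parameter regime:

| pipeline | canvas | content |
|---|---|---|
| `cr500` / `cr1000` | 180² (configurable) | one circular CR (r ∈ [1,30], A ∈ [2,2·10⁴] log-uniform, L=255) on a split-line background: dark side exponential(10)+1, light side 128 (500 Hz) or [32,153] (1000 Hz); σ_n ∈ [0,30] |
| `pupil500` / `pupil1000` | 180² | dark pupil (minor r ∈ [20,60], major ×[1,1.3]) + 1–4 CRs (minor r ∈ [4,12], ×[1,1.1]) anywhere, iris grey [64,179] / [32,153] |
| `eds2019` | 192² | sclera N(217,26) → iris ellipse (minor r ∈ [30,42.5], ×[1,1.3], N(77,16), raised-cosine edge 8–20 px) → collarette (r_col ∈ [0.3,0.6]·iris major, L ∈ [1.25,1.6]·L_iris) → pupil (minor r ∈ [10,30], A ∈ [2,2000], N(34,15)) → 1–8 small CRs; emits a pupil mask (clipped field ≥ 0.5) |
| `chugh` | 128² | gradient background [63,178], pupil (minor r ∈ [6,22.5], A ∈ [200,10⁵], exponential luminance), five CRs on a "house" constellation with 16% per-CR dropout, 1–5 spurious reflections |
| `eds2020` | 128² | as `chugh` with an eight-CR regular octagon (radius [0.15,0.4]·128, rotation ±0.57°), 20% dropout, pupil luminance 18 + Weibull(k=2, λ=25) |

Sampling rules:

* Interval parameters are uniform, except amplitudes, which are log-uniform
  — they span up to four orders of magnitude, and uniform sampling would
  almost never produce soft-edged features.
* Exponential/Weibull luminances are resampled if they exceed 255.
  Normal luminances are clipped into [0, 255].
* CR overlap: a CR closer to another than 1.25× the sum of their major
  radii is replaced by a fresh draw, up to 1000 replacements
  (`PlacementError` beyond that).
* The split-line border's closest approach to the CR center is uniform in
  [0, 2·r]; which side of the line hosts the CR is equiprobable.
* Constellations: house = rectangle (w ∈ [0.1,0.45]·128, h ∈ [0.5,0.6]·w,
  bottom width ×[0.05,0.2]) plus an apex h_r ∈ [0.2,0.5]·w above the top
  edge, identity 0 at the apex, clockwise; octagon identity 0 at the
  bottom-right vertex, clockwise. The constellation centroid sits at the
  pupil center plus an isotropic N(0, (0.05·128)²) offset; the pupil center
  itself is uniform within ±0.2·128 of the image center, and the joint
  placement is resampled until all vertices land on the canvas (the vertex
  positions, not visibility, define the identity labels, so dropout
  calibration stays exact).
* Dropout is an independent Bernoulli per CR; dropped CRs contribute
  nothing to the image and are labeled absent.
* Spurious reflections are rejection-sampled with acceptance probability
  `1 − min(G_pupil, 1)` using the pupil's actual amplitude, so they never
  land on the pupil plateau and are unlikely near it. (A unit-amplitude
  variant would give almost no suppression at the steep amplitudes these
  pipelines use.)
* EDS2019 coherence constraints not derivable from parameter ranges alone:
  the pupil's major radius is capped at 0.95× the iris minor radius and its
  center offset limited so the plateau stays inside the iris; the
  collarette center sits within 0.05× the iris minor radius of the iris
  center. The iris (including its soft edge) is kept fully on canvas.
* Stage 2 narrows distributions toward the target setup: feature centers
  within a 1.5-px span around the image center and exactly one CR
  (high-resolution pipelines); dropout 10%, rotation ±35°, ≤3 spurious
  (house); ≤3 spurious (octagon — its dropout and rotation are already the
  target-setup values).

Generators accept `render=False` to sample labels and parameters without
compositing pixels; distributional checks over 10⁴ draws use this mode.

## Post-processing

* Heatmap peaks are integer argmaxima (row-major tie-break); sub-pixel
  output is the regression CNN's job, and the pixel-level peak matches the
  pixel-error evaluation.
* Best-two CR selection takes the two identities with the largest
  max-logits (ties toward the lower index), independently per frame; a
  frame is valid iff at least two CR max-logits are ≥ 1. The threshold
  presupposes the heatmap target scale, which the training harness fixes:
  target maps are isotropic Gaussian bumps with peak exactly 1 (SD 1 px) at
  the rounded feature center, absent features all-zero.
* Probability-map → pupil: binarize at 0.99, fill holes (flood-fill
  complement; no opening/closing), keep blobs with area ∈ [25, 10000] px²
  and axis ratio ≤ 3, take the largest, report its center of mass and a
  total-least-squares ellipse fit to the sub-pixel boundary contour.
  The area/ratio defaults quantify otherwise-unstated "shape and size
  criteria" and are configurable.
* Adaptive cutouts: images are first downscaled ×2 (block mean). If an
  external pupil prior's confidence ≥ threshold, the cutout centers on the
  prior; otherwise a centered cutout is taken, a first inference pass
  locates the pupil, and a second cutout centers there. A cutout whose
  pupil center lies strictly closer to the edge than the fitted ellipse's
  major radius is re-centered once. Cutouts at borders use edge
  replication. The pupil prior is any callable returning (center,
  confidence); no specific detector is bundled.

## Thresholding baseline

Fixed dark/bright thresholds binarize the image; holes are filled; blobs
are filtered by area and axis ratio; the pupil is the largest dark blob,
the CR the largest bright blob within 1.5× the pupil blob's bounding radius
of the pupil center (the "relative location" rule, disableable). Centers
are blob centers of mass. CR cutouts (180², centered on the rounded
center) get a black mask outside radius 32 px (boundary inclusive); pupil
cutouts get a middle-grey mask outside 1.4× the fitted pupil ellipse.

## Data-quality metrics and calibration

* RMS-S2S precision: RMS of Euclidean sample-to-sample displacements in a
  200-ms window sliding one sample at a time; the reported value is the
  median over windows. A 200-ms window at rate f spans round(0.2·f)
  samples. Steps touching a missing sample are deleted pairwise; windows
  with no valid step are skipped. Axes combine as Euclidean steps (not
  per-axis RMS combined afterwards) — for i.i.d. noise of SD σ per axis the
  closed form is 2σ.
* STD precision: per window, sqrt(var_x + var_y) with the unbiased (n−1)
  estimator over valid samples; median over windows; closed form σ·√2.
* P-CR vector: pupil minus CR, missing when either is missing; timestamps
  must match exactly.
* Calibration: per output axis, least squares over the terms
  {1, x, y, x², y², xy} — six coefficients, so the 3×3 fixation grid (at
  h ∈ {−7,0,7}°, v ∈ {−5,0,5}°) is sufficient and any generating map inside
  the model class is recovered with zero residual. Rank-deficient designs
  raise.
* Accuracy: per fixation window, the Euclidean offset between the
  component-wise median gaze and the target; mean over fixations; empty
  windows are counted and skipped.
* Cumulative detection rate uses inclusive comparison (error ≤ threshold);
  mean pixel error multiplies predictions by the downscale factor first and
  excludes missing pairs.

## Training harness

A minimal numpy layer stack (3×3 same-padding conv via im2col, ReLU, 2×2
max pool, dense; Adam; MSE/MAE losses; BCE + Dice + focal for heatmap
configurations, with an optional positive-class BCE weight) implements the
training demos on one CPU. Batches are streamed: image i of epoch e always
comes from the substream keyed (seed, e, i), each image is shown once and
discarded, and two runs with the same seed are identical. Two-stage
training applies per-stage learning rate (stage 2 never higher),
exponential per-epoch decay (×0.97), early stopping on a pre-generated
fixed validation set (patience in epochs, stage-best weights restored), and
frozen-layer lists at stage start. Non-finite losses abort with a
diagnostic.

The full-scale architectures used on real eye-tracking data are recorded as
declarative specs — seven-conv CR/pupil CNNs with widths
(64,64,128,128,256,256,512) or (128,128,256,256,512,512,768) and dense
heads (64,32)/(64,64), and a residual heatmap U-Net (6+6 residual modules,
256 channels, one output map per feature) — with 3×3 kernels, ReLU and
pooling after every second conv layer as defaults where the source
architectures leave these unstated. Their parameter counts are reported by
`Sequential.n_parameters()` but not asserted: exact counts depend on
unstated kernel and input sizes.

### Desk-scale demo

The demo trains a small center-regressor — conv widths (16,32,64,64) with
2×2 max pooling after *every* conv layer (a single-CPU efficiency choice:
~6× fewer multiply-accumulates than pooling every second layer, with no
observed loss of sub-pixel capacity), dense (64), two linear outputs — on
64×64 second-stage single-CR scenes. The target is the CR center's offset
from the image center, which stage 2 confines to ±0.75 px per axis. Problem
sizes: up to 20 epochs × 1000 fresh images, batch 16, Adam at 1e-3,
patience 6, validation 300, evaluation on 500 held-out images. In
experiments this reaches ~0.13–0.5 px median error depending on seed;
always-predict-center would score ~0.6 px, so errors well below that mark
genuine sub-pixel readout from the Gaussian edge profile.

## Oracle and test design choices

* The centroid oracle (rendered CR scenes, 0.02-px bound) uses soft-edged
  features (plateau r ∈ [12,25] px, A log-uniform [2,50]) on a uniform
  background: a near-binary disk under 8-bit point sampling carries
  ~0.05–0.2 px of irreducible aliasing in its sampled centroid, so only
  soft edges spanning several grey levels can probe renderer geometry at
  this precision.
* The baseline-agreement check uses noiseless "well-separated" scenes:
  stage-2 (near-centered, fully visible) pupils of minor radius 20–40 px,
  CRs kept clear of the pupil and ≥15 px from the borders, iris grey
  ≥100 so the exponential pupil luminance almost never collides with the
  mid-way threshold. Per-scene thresholds are the midpoints of the known
  luminances, standing in for the per-participant threshold search used on
  real recordings (a grid-search example, not a library guarantee).
* Dropout calibration is checked against the 99% binomial confidence
  interval at n = 10⁴ per identity.

## What the generator does and does not emulate

The pipelines emulate luminance relations, feature shapes, constellation
geometry, sensor noise and 8-bit quantization. They deliberately omit
eyelids, eyelashes, skin texture, motion blur, interlacing, off-axis
distortion and reflections of scene content. Passing tests therefore show
that models and metrics behave correctly on the abstract feature model —
sub-pixel localization on these images demonstrates the training mechanism,
not performance on any real recording, which additionally depends on
matching the pipelines' luminance distributions to the target device.

## Known limitations

* The numpy training engine is single-threaded and CPU-bound; it is sized
  for the demo, not for the full-scale configurations.
* `prob_map_to_pupil` and the baseline assume a single dominant blob per
  feature; overlapping eyelid shadows on real data would need the
  configurable criteria retuned.
* Exponential-luminance truncation at 255 shifts the nominal mean by a
  negligible amount (< 10⁻⁹ relative at scale 10).
* The EDS2019 pupil-containment cap (0.95× iris minor radius) slightly
  narrows the printed pupil-radius range for the largest pupils inside the
  smallest irises; without it no coherent scene exists.
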