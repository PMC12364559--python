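# Methods

## Problem setting

Ecological monitoring produces video (underwater monitoring stations,
baited remote underwater video) and burst imagery (camera traps) in
which the background is static or slowly drifting while animals move.
Image object detectors take one three-channel frame at a time, so the
temporal signal is lost unless it is measured explicitly and re-encoded
into the image. `motionaug` implements that measurement and
re-encoding, plus the bookkeeping (manifests, splits, tuning, metrics)
needed to run it honestly on a labelled dataset.

All frames are `h x w x 3` RGB arrays in [0, 1]; 8-bit files map by
`value/255`. Frame offsets `Δt`, `Δt_b` are counted in frames of the
stored sequence for both video-derived and burst-derived data: for
video a frame is a fixed fraction of a second, for camera-trap bursts
it is one shot. Boxes are stored center-normalized (YOLO text dialect)
and converted to 0-based half-open pixel corners, so integer boxes have
exact widths and IOU arithmetic is exact.

## Movement measures

**Three-frame differencing.** The absolute form averages the deviation
of `F_t` from both neighbours; the directional form is centred at 0.5
and keeps the sign of change. The scale parameter `υ` (default 1;
useful range roughly 1–15) amplifies weak signals — small, slow or
low-contrast animals — at the cost of saturating strong ones. Values
are truncated to [0, 1] *after* scaling for all three differencing
measures, including the centred ones: a centred measure with `υ > 1`
can leave the colour range, and the augmented image must remain a valid
image. Truncation rather than renormalisation preserves the resting
levels (0 for FD_a, 0.5 for FD_d/BS_FD) exactly.

**Background subtraction.** The background estimate is the pixelwise
mean of `n_b` historic frames spaced `Δt_b` apart; with enough spacing
this averages transient foreground out. `BS_FD` is the signed,
υ-scaled distance from it, centred at 0.5. The alternative KNN
classifier is a deliberate simplification of production background
subtractors: each pixel's history buffer (default 50 frames) is its
reference sample, and the pixel is foreground when the majority of its
k = 3 nearest samples (Euclidean RGB distance) lie beyond a threshold
(default 0.08, i.e. ~20/255 per channel). Spatial neighbourhoods and
foreground-sample recycling are intentionally omitted; they depend on
implementation internals that are not well documented, and continuous
differencing measures outperform binary masks for this use anyway.

**Optical flow.** Flow is estimated between `F_t` and `F_{t+Δt}`
(forward; backward available) on luma. The built-in `block_match`
estimator is an exhaustive SSD search over integer displacements within
a radius (default 4) around each point of a coarse grid (default step
4, patch half-width 3), bilinearly upsampled to full resolution. Cost
is the mean squared difference over the overlap valid in both frames,
so border patches are comparable; candidate displacements are ordered
by magnitude and only a *strictly* smaller cost replaces the incumbent,
so ties resolve to the smallest displacement and static input yields
exactly zero flow. The `farneback` estimator delegates to OpenCV when
that library is importable and raises a capability error otherwise.
Direction is `θ = atan2(v_y, v_x)` wrapped to [0, 2π) — the
conventional two-argument form, since a one-argument arctangent cannot
resolve the quadrant. Encoding: `magnitude1` stores `clip(r/r_max)`;
`hsv3` maps θ to hue and `clip(r/r_max)` to value at full saturation,
so still pixels are black regardless of their undefined direction.
`r_max` defaults to the frame's 99th percentile of `r`, which keeps a
single outlier vector from crushing the rest of the scale; a frame with
no flow maps to zeros.

**Boundary policy.** The first/last `Δt` frames of a sequence lack a
neighbour and early frames lack background history. The default
`clamp` policy substitutes the nearest existing frame (the KNN buffer
shrinks instead), so every labelled frame can be augmented; `strict`
raises, naming the missing index or the available history. Clamp hits
are counted per image in the run log.

## Augmentation

`all` replaces the whole image with the 3-layer measure (flow is
HSV-encoded, the KNN mask replicated). `red` replaces only the red
layer with a 1-layer measure — frame-differencing maps collapsed by
averaging their three layers, flow reduced to magnitude, the KNN mask
as-is — motivated by the spectral absorption of red light in water.
`pca` compresses colour to two components and stores movement in the
freed red channel.

The PCA colour model is fitted once per dataset on pixels pooled from
`n_t` training-split frames (default: all, capped at 500, sampled
without replacement under the config seed) into an `h·w·n_t × 3`
matrix. The top-2 principal directions are whitened (scores scaled to
unit variance, `ddof = 1`). Whitened scores are unbounded, so each
component passes through an affine range map fitted to its 0.25th and
99.75th percentiles on the training sample — 99.5% of training scores
land in [0, 1] — then clips. Two numerical conventions make the model
reproducible: each component is oriented so its largest-magnitude
coefficient is positive (eigenvector sign is otherwise arbitrary), and
a component whose variance is negligible relative to the total gets
whitening scale 0 and maps to the constant 0.5 (grey-world footage,
e.g. infrared night bursts, is effectively one-dimensional in colour;
only a fully constant pixel pool is an error). The model persists as
JSON and is refitted never — validation and test images are transformed
with the frozen training-split model, and the run log records exactly
which images the fit saw.

Labels are never touched: augmentation recolours pixels but moves
nothing, so label files are byte-copied.

## Tuning and evaluation

The tuning grid multiplies only the fields a method actually uses, so
`raw` is a single configuration. Selection reads validation-split
records only and reports an audit of the splits it consulted; ties
break towards smaller `Δt`, then smaller `υ`, then mode order
all < red < pca (simpler and cheaper configurations win ties).
Two-stage selection — motion parameters first at a fixed mode, then the
mode with parameters frozen — is available and mirrors how one would
tune with an expensive detector in the loop; the default single-stage
argmax is exact when the full grid has been evaluated.

AP uses greedy matching in descending score order (stable on ties),
best-IOU unmatched ground-truth box, each box claimable once, and
all-point interpolation of the precision-recall curve
(precision = TP/(TP+FP)). Per-class AP is non-increasing in the IOU
threshold under this matching; mAP at a threshold averages classes with
at least one ground-truth box; classes with detections but no ground
truth contribute nothing and are logged. The implementation is checked
against an exhaustive evaluator that re-runs matching from scratch at
every score cutoff.

## Synthetic fixtures

The generator renders moving rectangles/ellipses of known geometry over
uniform, gradient or textured backgrounds, with optional underwater
cast (red channel multiplied by a factor ≤ 0.2), monochrome rendering
(BT.601 luma replicated, emulating infrared night shots) and i.i.d.
Gaussian pixel noise added last and clipped. Trajectories are
per-frame integer displacements, so ground-truth boxes follow by exact
arithmetic. Default test scenes use a 12×12 object at contrast ≥ 0.3
moving 2 px/frame on 64×64 frames with noise σ = 0.02 — values chosen
once as representative of a clearly-visible animal in modest sensor
noise; noise statistics of real monitoring datasets vary widely and are
not calibrated here.

What the fixtures do **not** emulate: camera motion, illumination
change, water caustics, compression artefacts, non-rigid animal motion,
and occlusion. Passing tests therefore demonstrate that the measures
compute what they claim and that the pipeline is deterministic and
leak-free — not that augmentation improves any particular detector on
real footage, which depends on dataset size and class rarity and must
be established per dataset via the tuning workflow.

## Problem sizes

The test and acceptance runs use deliberately small instances — 8×8×3
sequences for oracle equivalence (100 of them), 64×64 scenes for
recovery (20 seeds), ≤10-box instances for the evaluator cross-check
(1,000), and a 20-image dataset for the end-to-end determinism check —
sizes at which the independent scalar-loop references are exact and
fast while still exercising every code path.

## Known limitations

* PNG folders are the canonical sequence container; video decoding is
  delegated to imageio/codecs and carries no bit-exactness guarantee.
* 3-layer motion maps persist as 8-bit PNG (the encoder has no 16-bit
  RGB mode); single-layer maps use 16-bit greyscale. The sidecar
  records the bit depth.
* The block matcher recovers integer displacements only and, like all
  local matchers, is blind inside large untextured regions (the
  aperture problem); there it returns the zero-displacement tie-break.
* The KNN simplification is per-pixel; it will flag more noise than
  production implementations with spatial support.
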