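# Methods

## The simulation model

`spvsim` models the perceptual front end of a visual prosthesis as a fixed
square grid of independent electrodes. Each electrode integrates the light
of its image region, reports one of a small set of gray levels, and either
works for the whole session or is permanently dead. The rendered percept is
a field of round, tangent, flat-intensity light discs on black. This is a
deliberately idealized model: no current spread, no phosphene elongation or
distortion, no temporal fading, and no psychometric brightness mapping —
each of which would sit between the quantized grid and the raster if added.

Defaults are the configuration the enhancement techniques were evaluated
under: a 32 × 32 grid (around the reported threshold for scene
recognition), 8 gray levels (patients reliably distinguish roughly 4–12),
a 20° circular visual field, a 10% dropout rate, round phosphenes with zero
inter-phosphene gap, and dropped sites rendered black.

## Stage-by-stage choices

**Grayscale.** BT.601 luma (0.299 R + 0.587 G + 0.114 B), rounded half-up.
The conversion convention is not dictated by the model; BT.601 is the
dominant default in imaging toolchains.

**Field-of-view mask.** No pixels-per-degree calibration is available for
an arbitrary input image, so the 20° field is realized geometrically as the
inscribed disc of the frame: diameter `min(h, w)`, centered on the frame
center, with a pixel inside when its *center* lies at distance ≤ radius.
The `field_of_view` value is carried as metadata only. Under this rule the
in-disc pixel fraction converges to π/4 on square frames (within 1% at
512²), and every membership question is unambiguous, including degenerate
1 × 1 frames (inside).

**Edge sharpening.** Canny via scikit-image with σ = 1.4 (the classical
default; the gradient operator is a derivative of a Gaussian and no σ is
prescribed by the model) and hysteresis thresholds 0.1/0.15 as fractions of
the full gradient scale. The edge layer is overlaid *saturating*: edge
pixels become 255 rather than being added arithmetically — with only 8
output levels, anything weaker than saturation risks being quantized away.
On an ideal step edge this implementation marks the two columns abutting
the discontinuity (≤ 2 px per row); edge counts are invariant under
intensity inversion.

**Corner emphasis.** FAST is implemented in-package because its exact
semantics matter here: a pixel is a corner when ≥ N contiguous pixels of
the radius-3, 16-pixel Bresenham circle are all brighter than the center by
more than t·255 or all darker, with t = 0.2 on the normalized scale and
N = 12. The per-corner score is the largest threshold that preserves
cornerness (max over arcs of the minimum margin); 3 × 3 non-maximum
suppression follows, with equal scores resolved in row-major order, then
corners below `min_quality` (0.1) of the maximum score are dropped. The
whole detector is cross-checked against a brute-force segment-test oracle
in the test suite. One geometric consequence worth knowing: a 90° corner
(any axis-aligned or rotated square) subtends exactly 11 of the 16 circle
pixels, so the N = 12 test by construction fires only on corners sharper
than 90°; the test suite pins this behavior (4 corners of a square at
N = 11, none at N = 12). Detected corners are dilated to 3 × 3 white dots —
a single white pixel would vanish at 32 × 32 phosphene resolution.

**Clip-art substitution.** Clip arts are high-contrast grayscale
silhouettes keyed by class label (a directory of `<label>.png`, or the
built-in synthetic set). The art is resized to the detection's bounding box
by nearest-neighbor sampling, which preserves hard silhouette boundaries
through the later quantization; the bbox complement is untouched. Object
detection is a pluggable `image -> [Detection]` callable; the bundled stub
echoes ground truth registered by the scene generator, and a trained
detector can be slotted into the same contract.

**Dropout.** Exactly `round(rate · cells)` sites are drawn uniformly
without replacement by a seeded generator — the rate is exact and the map
reproducible bit-for-bit per seed, mirroring fixed electrode malfunction
within a session (102 sites at the 32 × 32 / 10% defaults). A per-site
Bernoulli draw would make the rate only approximate.

**Dropout handling.** The object's binary support at grid resolution is
cross-correlated (valid region) with the availability matrix
(1 − dropout indicator); the score at a placement is then exactly the
number of working sites under the support, so the argmax is the
minimum-dropout position. Correlating the raw dropout indicator would
invert the objective. Valid-region correlation means an object is never
placed straddling the field edge. Ties are broken by smallest Euclidean
distance to the object's original center, then row-major order — keeping
localization faithful and results deterministic. The support is the
object's silhouette (pixels darker than the midpoint between the region
minimum and the scene background estimate, reduced by block-any), falling
back to an all-ones box for featureless regions. The placement search runs
at grid resolution and the chosen shift is scaled to pixels; dropouts only
exist at electrode sites, so a finer search adds nothing.

Inside the pipeline, candidate placements are additionally restricted to
those whose implied pixel bounding box stays fully inside the frame and
does not collide with an already-placed object (multi-object scenes are
processed left to right, each box translated separately). The standalone
`apply_translation` clamps an off-frame shift to the border and logs a
warning instead, for direct use. Vacated pixels are refilled with the
image median (≈ the scene background) so a moved object leaves no black
ghost that would read as dropout.

**Reduction and quantization.** The masked frame is partitioned into n × n
near-equal blocks; each cell takes its block's arithmetic mean (half-up
rounding) — the least surprising estimator of a cell's light content.
Quantization uses bin `floor(v · 8 / 256)` mapped onto the codebook
{0, 36, 72, 108, 144, 180, 216, 252}; this bin rule reproduces that printed
codebook exactly, is idempotent and monotone, and covers all 8 levels over
the 0–255 input range.

**Rendering.** Each working cell holds a filled disc of diameter equal to
the cell (gap 0 ⇒ tangent discs), flat intensity, black background; dropped
cells are entirely black. Disc membership uses the same pixel-center rule
as the field-of-view mask.

## Pipeline ordering

Enhancement order is clip-art substitution → edge sharpening → corner
emphasis → dropout-handling translation, per object; the field-of-view
mask is applied *after* translation so dropout handling cannot move an
object outside the visible disc, and the dropout map itself is applied at
render time. Edge and corner detection run on the (possibly substituted)
bounding-box region, so under combined conditions the clip art — not the
raw object — is sharpened, which is what the combined conditions intend.
Whether corners should be detected on the raw or already-edge-sharpened
region is an open choice; this package detects them after sharpening,
which slightly favors silhouette corners.

## The synthetic scenes

The generator emulates the tabletop setup the techniques were evaluated
in: dark (intensity 40) parametric silhouettes — bottle, cup, banana, car
toy, laptop, plus backpack and chair for navigation scenes — on a light
background (230, not 255, leaving headroom so white edge overlays remain
distinguishable after quantization). Shapes are analytic rectangles,
ellipse arcs and crescents, so scenes are deterministic and ground-truth
bounding boxes are computed from the rendered mask itself (hence always
tight). The standard set holds 5 single-object scenes, 3 pairs and 3
navigation objects of small/medium/large size, at 256 × 256 by default —
an 8-pixel image block per grid cell.

What the fixtures deliberately do not model: lighting, shadows and
reflections, texture and clutter, perspective, occlusion, or detector
error (the stub detector is perfect by construction). Tests passing on
these scenes therefore validate the *pipeline mechanics* — masking,
enhancement, placement optimality, quantization, determinism — not
real-scene recognition performance, which requires observers.

## Session metrics

Recognition accuracy is the percentage of trials whose reported label
matches the truth; grasping accuracy scores each trial 100 (correct grasp)
or 0 and averages. A near miss — final distance within the 10-cm margin
without a correct grasp — scores 0 but its time still counts as a valid
attempt. Trials with no successful outcome are censored at the protocol
maximum (120 s single-object, 240 s multi-object, 180 s navigation): how
unsuccessful trials enter the reported mean times is not fully specified
by the protocol, and treating them as consuming the whole window is the
conservative reading. Means use compensated summation so metrics are
exactly permutation-invariant.

## Problem sizes and determinism

Everything is CPU-light: the full test suite (including 50-seed exhaustive
placement enumeration on grids up to 12 × 12, 20-seed FAST-vs-oracle
comparisons, and all 8 condition presets over all 11 standard scenes, run
twice for byte-reproducibility) completes in a few seconds. All randomness
flows through `numpy.random.default_rng(seed)`; a frame render is a pure
function of (image, config), and the CLI writes byte-identical PNGs for
identical invocations.

## Known limitations

- The degree→pixel mapping of the visual field is the inscribed circle of
  the frame, a stand-in in the absence of optical calibration.
- Phosphenes are flat discs; no current-spread, brightness or shape model.
- The dropout model is binary and static; no progressive degradation.
- The clip-art registry is label-keyed 2-D art; no perspective matching.
- The stub detector requires scenes whose ground truth was registered (or
  explicit detections/sidecars); it is a test harness, not a detector.
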