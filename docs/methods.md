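# Methods

This note records the models, conventions and numerical choices behind
`spinalign`, in the spirit of a methods appendix: what is computed, under
which assumptions, and which decisions were genuinely open.

## Landmark schema and coordinates

The vocabulary has exactly 45 members: 22 specific points (C2 dens centre,
selected endplate corners of C2/C7/T1/T5/T12/L1/L4, the two sacral-endplate
edges, both femoral-head centres) and the 23 vertebral-body centres C2–L5.
Each member carries a region tag (cervical/thoracic/lumbar/sacral/femoral);
the subset wired into parameters is exposed as `USED_FOR_PARAMETERS` rather
than a count, because published descriptions of such schemas disagree on
how to partition "specific" versus "centre" points.

Coordinates are 0-based pixel indices with y increasing downward (cranial =
−y), matching image-array indexing. Physical scale is an isotropic
`pixel_spacing` in mm/px; mm-valued parameters require it, and images
without any scale are rejected rather than silently assumed. Lateral films
can face either way, so the patient's anterior direction is an explicit
field (`+x` by default) used by every sign convention below.

Preprocessing resizes with one scale factor (never stretching), pads
left/right equally and any vertical remainder at the bottom, and records an
invertible affine (`forward`/`inverse` agree to < 1e−9 px) so predictions
map back to original pixels.

## Parameter geometry

All 18 parameters are computed from two-argument arctangents of explicit
direction vectors; the wiring is centralised in `geometry.py` so it can be
re-audited in one place. Conventions: lordosis and kyphosis positive;
offsets (SVA, cSVA, OD-HA, Barrey numerator) anterior-positive; slopes (SS,
T1S) positive when the anterior endplate edge is caudal — the usual
clinical reading, which makes typical adult values positive. The hip axis
is the midpoint of the femoral-head centres; the C7 plumb line drops from
the C7 centroid; SVA is referenced to the posterior sacral-endplate edge
and the Barrey denominator to the anterior-signed hip-to-posterior-corner
offset. Published definitions are ambiguous about the last two reference
choices; both are flagged in the wiring table and trivially re-wireable.

With these conventions `PI = PT + SS` holds *exactly*: PT is the
anterior-signed angle of the sacral-midpoint→hip ray from the downward
vertical, SS the posterior-signed angle of the caudal endplate normal, and
PI their directed sum. Under a rigid rotation of the film the shape angles
(PI, LL, CL, GTK, PTK, MTK, L4SL, SSA, GT, TPA, LPA) are invariant, while
the gravity-referenced ones shift by the rotation — PT one way, SS/T1S/
OD-HA the other, exactly preserving the decomposition. These invariances
are enforced by property tests.

## Heatmaps, DSNT and losses

DSNT reads a softmax-normalised heatmap as a distribution over the grid
`X_j = (2j − W − 1)/W` (1-based), so coordinates live strictly inside
(−1, 1) and are resolution-agnostic. The scalar reference implementation
uses compensated summation (`math.fsum`) so symmetric heatmaps map exactly
to zero; the batched training path is the same computation vectorised.

The regression objective is the mean over the 45 landmarks, summed over
both stages, of Wing losses on the x and y residuals. The Wing loss is
`w·ln(1 + |x|/ε)` for `|x| < w` and linear with a continuity-matched offset
beyond; defaults `w = 10`, `ε = 2` are interpreted in heatmap pixels, so
the trainer scales normalised residuals by half the heatmap grid dimension
before applying it. A printed form of this objective carries a leading
minus sign on the non-negative Wing terms; minimising that form would
diverge, so the positive mean is used.

Heatmap regularisation adds `λ ×` the mean Jensen–Shannon divergence (nats,
bounded by ln 2) between second-stage heatmaps and target splotches;
`λ = 1.0` by default (no published value exists) and stage 1 is left free
to form arbitrary shapes. Targets are Gaussian
`∝ exp(−(Δx² + Δy²)/2σ²)` or L1-profile exponential; the exponential's
decay constant is chosen so both kinds reach half their peak at axial
radius `σ·√(2 ln 2)` — the property the two kinds are designed around. (A
printed exponential form with denominator `2σ` would put the half-max at
`2σ` instead, contradicting that design; the stated property wins here.)
The width grid derives from the mean inter-vertebral centre distance `d`:
base width `σ = d/6` rounded to one decimal (a six-sigma splotch confined
within one vertebral spacing; 41.2 px → 6.9), with halvings σ, σ/2, σ/4,
giving the 7-candidate grid {Gaussian, exponential} × 3 widths + none.
σ is interpreted at input resolution and rescaled to the heatmap grid.

## Network

A residual-block architecture with exactly 25 trainable residual blocks in
the default configuration: a stem convolution (stride 2), three encoder
levels at 1/4, 1/8 and 1/16 resolution, lateral 1×1 convolutions with
upsample-and-add fusion back to the heatmap resolution (1/4 by default),
a stage-1 head producing 45 heatmap logits, and a stage-2 refinement chain
over the concatenation of fused features and stage-1 logits. Each residual
block is two 3×3 convolutions with batch normalisation and a skip path
(1×1 convolution when shapes differ). Published diagrams of this family
omit channel widths and the block-to-stage assignment, so the *census* of
blocks is the tested contract and widths/depths are configuration
(`base_channels = 32`, `stage2_refinement_depth = 4` by default; the block
budget is distributed to the encoder after the structural slots are
filled). The stage-2 entry is batch-normalised: stage-1 logit magnitudes
grow as that head sharpens and would otherwise saturate the refinement
path — without this the second stage stalls on a few landmarks while the
first keeps improving.

Both stages end in DSNT; inference keeps only stage-2 coordinates.
Ensembles average member predictions unweighted, per landmark, in original
pixel coordinates. Checkpoints embed the configuration and a schema
version. Normalisation is standard single-device batch normalisation;
multi-GPU variants are out of scope.

Everything runs on a small reverse-mode autodiff engine written for this
package (float64, im2col convolutions, hand-written backwards for the
fused ops), since no deep-learning framework is a dependency. Every
primitive's gradient is tested against central finite differences, and the
end-to-end loss gradient is spot-checked the same way through the full
two-stage model.

## Training, weighted error and selection

Training uses Adam (lr 0.005, dropped to 0.0005 at epoch 100), batches of
paired image/landmark samples, and the published augmentations: random
similarity transforms about the canvas centre (scale 0.8–1.0, rotation
±30°) applied identically to pixels and landmarks, plus Gaussian blur of
strength 0–0.1. The blur strength's units are not published; it is read
here as σ = 10×strength pixels (0–1 px), a mild perturbation. Draws that
push any landmark off the canvas are rejected and redrawn. Default
schedule: 120 epochs with early stopping after 20 epochs without
improvement of the validation selection metric (the metric below, not the
training loss); the best-scoring weights are restored at the end.

The weighted localisation error divides each landmark's Euclidean error by
the distance from that annotated landmark to its nearest annotated
neighbour on the same image (recomputed per image), making errors
dimensionless and similarity-invariant: a value of 1 means the prediction
could plausibly have reached the neighbouring landmark. Per landmark the
median over images is taken; a candidate's score ξ̃ is the maximum of those
medians, and selection minimises ξ̃. The five-fold cross-validation split
is seeded and stratified by phantom pathology class. The ensemble keeps
the top two candidates by ξ̃.

Per epoch the trainer also logs the per-area mean spread of stage-1
heatmaps (cervical/thoracic/lumbar over vertebral centres, plus the
femoral heads), the input to the learning-speed analysis.

## Evaluation statistics

* Letter-value (boxenplot) quantiles: level k ≥ 1 covers
  (2^−(k+1), 1 − 2^−(k+1)) — quartile box, eighths, sixteenths, … — around
  the median; type-7 linear-interpolation quantiles throughout (no
  definition is published; this is numpy's default).
* Parameter errors: absolute differences summarised as mean (SD) and
  median (IQR); Pearson r with constant-input guarding; two-sided Wilcoxon
  signed-rank with zero differences dropped (p = 1 by convention when all
  differences vanish; scipy chooses exact vs normal approximation).
* ICC: two-way random effects, absolute agreement, single measurement —
  ICC(2,1), computed via pingouin and cross-checked in the tests against a
  from-scratch ANOVA mean-squares oracle. Grades: excellent (≥0.9), high
  (0.7–0.9), moderate (0.5–0.7), low (0.25–0.5), poor below. Heatmap axes
  are ordered by average-linkage hierarchical clustering on Euclidean
  distances, oriented so higher agreement sorts last.
* Heatmap spread: `√((Var_x + Var_y)/2)` of the normalised heatmap's
  marginals, in pixels (no published estimator; this isotropic summary is
  the natural one). Learning speed: least-squares slope of log SD vs log
  epoch over epochs 10–100, γ = −slope, with adjusted R² and slope p-value
  from the OLS fit; per-landmark SDs are averaged into areas before
  fitting.

## Synthetic phantoms

The generator emulates a whole-spine lateral film: 23 vertebral bodies
stacked caudal→cranial along endplate-tilt profiles that realise requested
cervical lordosis, thoracic kyphosis, lumbar lordosis and pelvic incidence
*exactly* (the constrained endplates are pinned; intermediate ones get ±1°
jitter), a sacrum whose superior endplate defines SS (taken as 0.696·PI,
the typical adult share), a hip axis placed to realise PI = PT + SS, and
two offset femoral-head circles whose midpoint is that axis. Bodies are
slightly wedged trapezoids growing ~3 %/level caudally; everything is
fitted into the canvas by an angle-preserving similarity. Landmarks are
exact by construction, which closes the generator/measurement loop (PI,
LL, GTK recovered to ~1e−13°; the 2° acceptance margin covers future
rendering-derived annotations).

Pathology classes mirror a clinical dataset's composition (scoliosis
47 %/kyphosis 21 %/implant 32 % in the sampler): scoliosis as mid-thoracic
ghost overlap and local blur (how a coronal curve shows on a lateral
film), kyphosis as a hyperkyphotic curvature draw (55 ± 8°), implants as
bright posterior rods with screws over nine levels. The class sampler
couples the kyphosis draw to the lumbopelvic draw so sampled spines remain
stackable. Default curvature means follow typical adult values (PI 51.6°,
LL 47.0°, GTK 37.7°, CL 9.4°).

What the phantoms do *not* model: projective geometry and divergent-beam
magnification, realistic tissue contrast and scatter (the intensity model
is flat fills + Gaussian/speckle noise + cartoon occluders), anatomical
shape variation beyond tilt/size profiles, anomalous vertebral counts, and
paediatric unfused sacra. Tests passing on phantoms therefore demonstrate
the *pipeline's* correctness (geometry, losses, training mechanics,
statistics), not clinical-grade localisation on real films.

## Problem sizes and degenerate inputs

CPU-scale configurations are used throughout the test suite and the
acceptance script: a 216×120-px input with 12 residual blocks and 8 base
channels for learning runs (200 phantoms / 15 epochs in the suite, 120 /
10 in the acceptance script), and a 64×32 "micro" model for structural and
gradient tests. These are the package's own choices of demonstration
scale; the default 864×480/25-block configuration is exercised
structurally (census, parameter counts, initialisation determinism).

Degenerate inputs raise typed errors rather than returning garbage:
zero-length lines, coincident femoral heads, zero sacrofemoral distance
(Barrey undefined), duplicate annotated landmarks (weighted error
undefined), unnormalised heatmaps, non-positive SDs in log-log fits,
constant rating tables (ICC undefined), curvatures that fold the phantom
spine, and NaN training losses (abort with diagnostics).

## Known limitations

* The phantom realism gap above; no claim of clinical performance is made
  or tested.
* The geometry wiring follows standard clinical definitions where sources
  are ambiguous (SVA/Barrey reference corners); re-wiring is a one-line
  table change.
* The autodiff engine is float64 and single-threaded beyond BLAS; training
  the full 864×480 model is possible but slow on CPU.
* Early stopping monitors the selection metric on a single validation
  split inside `train`; full k-fold orchestration is provided by
  `kfold_split` + `select_model` but is the caller's loop.
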