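# Methods

This note records the model, the numerical choices, and the places
where the design was genuinely open, in the package's own words.

## Detection model

The detector is a single-stage, anchor-free network over three scales
(strides 8, 16, 32).  Five backbone stages halve resolution each; every
block is SiLU(BN(conv)).  The neck is a standard FPN top-down pass
followed by a PANet bottom-up pass; each fusion node concatenates two
resized paths and fuses them with one 3×3 block.  Each head emits, per
grid location, four box log-distances (l, t, r, b), one objectness
logit, and six class logits.  Boxes decode as
`exp(raw)·stride` distances around the location centre; class
probabilities are a softmax; a detection's ranking score is
objectness × max class probability (the class-confidence vector alone
does not define a ranking scalar).

### Elastic width and depth

The architecture is parameterized by λ_d ∈ {0.75, 1.0, 1.25} and
λ_w ∈ {0.5, 1.0, 1.5}.  Channels are selected at build time as
`clamp(round(λ_w·C_base), D_min, D_max)` with the admissible band
defaulting to `[round(0.5·C_base), round(1.5·C_base)]`, mirroring the
width set; rounding is round-half-up so the mapping is deterministic.
The original framing of "channels determined at run-time" gives no
selection signal, so width is config-driven (per-stage overrides are
possible through the schedule file) — a documented divergence from a
literal run-time policy, chosen because it keeps builds reproducible
and profiles well-defined.  Elastic convolutions store a super-kernel
of D_max filters and slice the first D_out, which makes the width axis
testable: narrowing never changes retained channel values.

### Deformable convolution

Deformable blocks compute `f(ξ₀) = Σ_{ξ∈S} ω(ξ)·g(ξ₀+ξ+Δξ)` with
bilinear interpolation at fractional positions and zero contribution
outside the map.  The displacement field Δξ (two channels per base
offset) is predicted by a parallel plain 3×3 convolution over the same
input — the established deformable-convolution construction; its
zero-initialization makes an untrained layer exactly a standard
convolution, which is also the main correctness oracle.  Deformable
blocks are placed in the last block of stages 3–5 and in the four
fusion blocks: the highest-level features, where receptive-field
geometry matters most, at bounded cost.  Stride-2 (downsampling) convs
are never deformable.

### Fusion pruning

Each fusion node scores its incoming paths by the L1 norm of the fuse
convolution's weight slice for that path, normalized over incoming
paths, and drops paths scoring below ε (default 0.01); the strongest
path always survives.  Pruning is structural (the weight columns are
removed) and applied once per evaluation pass, never during training.
ε has no published value; 0.01 removes only near-dead paths.

### Base schedule and the published budget

The base schedule — channels (96, 168, 224, 224, 248), depths
(4, 6, 6, 3, 2), head width 96 — was calibrated by scripted search
(`scripts/calibrate_schedule.py`) so the λ = 1.0 profile at 256×256
lands on 12.4 M parameters and 30.1 GFLOPs, the published budget for
the full-scale model.  Hitting a FLOPs/parameter ratio of ≈2400 forces
compute toward the high-resolution stages, hence the comparatively wide
early stages.  The FLOPs sum counts a multiply–accumulate as 2
operations over convolution layers only (offset branches included;
activations, BN and NMS excluded).  The bilinear-sampling cost of
deformable layers (4·|S| multiplies per output location per input
channel) is reported as a separate supplement so the headline number
stays a pure convolution sum, and both readings are visible in the
profiler output.

## Loss

`L_total = λ_reg·L_reg + λ_cls·L_cls + λ_det·L_det` with
(0.05, 1.0, 1.0).

* `L_det` — CIoU, `1 − IoU + ρ²/c² + α·v`, averaged over positive
  locations.  The balance factor α = v/((1−IoU)+v) is differentiated
  through (rather than the detached-α convention) so the analytic
  gradient matches finite differences of the written loss exactly.
* `L_cls` — softmax cross-entropy at positive locations, plus the
  objectness binary cross-entropy over all locations.  Anchor-free
  detection needs an objectness channel that the categorical loss does
  not cover; it is bookkept inside the classification term.  A focal
  variant of the objectness term exists behind `focal_gamma` and is off
  by default.
* `L_reg` — mean (not sum) over offset vectors of ‖Δp‖², so λ_reg's
  effect is resolution-independent.

Epoch logs carry both the weighted total (which trains) and the
unweighted sum of the three terms: published epoch tables total their
columns without the λ weights, and logging both keeps either reading
reproducible.

Target assignment is centre-based: a location is positive iff its
centre lies inside a ground-truth box whose longest side falls in the
scale's range ((0, 64), (64, 128), (128, ∞) pixels); the smallest
containing box wins ties.  The head's objectness bias initializes to −4
(positives are rare; this stabilizes the first epochs).

## Evaluation

Matching is greedy, one-to-one and class-strict for P/R/F1/AP; the
confusion matrix alone uses class-agnostic matching so cross-class
confusions are recordable.  Score ties break by input order, IoU ties
by first truth index.  AP is the exact area under the precision
envelope (all-point); a 101-point COCO-style variant is available by
flag and is the default for the 0.5:0.95 range.  Detection has no
natural true-negative count, so the accuracy's C_neg is defined as the
number of prediction-grid locations that are truth-negative and score
below the confidence threshold — this makes accuracy depend on grid
resolution, which is documented rather than hidden.

## Synthetic smear scenes

The generator emulates the statistical structure of a clinical smear
corpus, not its appearance.  Cells are flat-shaded ellipses with
class-specific geometry: near-circular pale RBCs with central pallor,
larger nucleated WBCs, small platelet specks, and abnormal variants
that differ by a controlled morphology delta — strong eccentricity
(aspect 0.38–0.55) for ARBC, enlargement plus a multi-lobed nucleus for
AWBC, roughly doubled speck size for APL.  Per-image counts are Poisson
with per-class means derived by splitting the reference per-image group
means (7.9 normal, 3.4 abnormal) proportionally to the corpus'
per-class annotation totals, truncated at 38 per image; overlap is
allowed for a configurable fraction of cells (default 0.3).  Bounded
per-image stain jitter (±5% channel gain) and additive Gaussian noise
(σ = 0.02) are the only photometric effects.  (seed, config) determines
every generated byte.

What passing tests on these scenes do **not** show: robustness to real
staining variability, focus artifacts, cell clumping, or the subtle
morphology that distinguishes clinical abnormality classes.  The scenes
establish that the architecture, losses and metrics are implemented
correctly and that the detector can learn a six-class localization task
end to end — not clinical performance.

## Preprocessing and augmentation

Channel statistics (population mean/std, ε-guarded at 1e-8) come from
the training split only and are stored in the checkpoint.  Training
augmentation is restricted to mild affine transforms — rotation
U[−15°, 15°], isotropic scale U[0.9, 1.1], translation within ±10% of
the extent — composed rotate → scale → translate about the image
centre with bilinear resampling and zero padding (the pivot and
interpolation are implementation choices; the parameter set is fixed).
Boxes map by transforming their four corners and taking the
axis-aligned enclosure, clipped to the image; boxes keeping less than
20% of their area are dropped.  Colour jitter, elastic deformation and
intensity distortion are deliberately never applied — they would alter
diagnostically relevant morphology.  Note the corner-mapped enclosure
of a rotated box necessarily over-covers an elliptical cell; at ±15°
this inflation is bounded (≤ ~50% area for a circle) and consistent
between training and evaluation.

## Training loop

SGD with momentum 0.937 and cosine learning-rate decay to 5% of the
initial value (optimizer and schedule are unpublished for the original
model; these are the conventional one-stage-detector settings), batch
size 16 by default and 8 for the scaled-down study, weight decay 0.
The offset branches of deformable blocks train at 0.1x the global
learning rate: without this damping the sampling geometry drifts faster
than the features it samples (offset norms spike in the first epochs),
a known instability for which the reduced offset learning rate is the
established remedy.
Everything is seeded: weight init, shuffling, augmentation.  Runs are
single-threaded and bit-reproducible for a fixed seed and BLAS.
Checkpoint selection is by best validation mAP@0.5, evaluated every
`eval_interval` epochs (validation loss and the grid-location accuracy
are logged on the same cadence; with no validation split the training
split stands in).  Ablation switches (`aug`, `deform`, `elastic`)
produce structurally comparable runs for augmentation-off, plain-conv,
and fixed-schedule variants.

## Scaled-down study sizes

The end-to-end study trains the λ_d = 0.75, λ_w = 0.5 model on 128²
synthetic scenes — 200 training and 50 held-out — for 30 epochs
(~750 SGD steps), reaching mAP@0.5 ≈ 0.86; the identically trained
no-deformable ablation lands at ≈ 0.84.  The gap is modest at this
scale — flat-shaded synthetic cells leave limited geometry for offset
learning to exploit — so the comparison is directional rather than
dramatic.  These sizes were chosen so the whole study, both runs
included, completes in well under half an hour on one CPU core while
leaving every class represented in the held-out split.

## Known limitations

* The NumPy engine trains small models on small images; it is a desk-
  scale research instrument, not a production trainer.
* mAP@0.5:0.95 is much lower than mAP@0.5 on synthetic scenes: with
  8–25 px cells, one pixel of box error costs several IoU points, so
  high-threshold APs fall quickly.  The same effect exists for small
  objects in real benchmarks.
* Platelets sit near the stride-8 grid's resolution floor; their AP
  dominates the residual error at the study scale.
* The NMS rule is class-wise (touching cells of different classes are
  legitimate in smears); whether the original procedure scoped
  suppression by class is unstated.
* Group-aware splitting: the dataset manifest records a per-scene
  acquisition-batch id (consecutive groups of ten scenes), but splits
  are assigned per scene; synthetic scenes carry no real batch
  structure to leak.
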