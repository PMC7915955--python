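# Methods

`adaptseg` is a desk-scale implementation of a deep-learning
auto-segmentation workflow for adaptive radiotherapy (ART) of the head and
neck: synthetic paired planning/adaptive CT phantoms, a two-step 3D
fully-convolutional DenseNet segmentation pipeline, matched (continual) vs
unmatched (conventional) training protocols, quantitative contour metrics
with the accompanying statistical procedure, and blinded subjective
(Turing-test) scoring.  Everything runs on one CPU in minutes; all grid
sizes, network sizes and epoch counts are configuration, with the clinical
profile (320 x 256 x 130 voxels, layers [3, 4, 4, 5, 7], growth rate 12,
250/200 epochs) as defaults and small profiles used for benchmarks.

## Coordinate convention

0-based voxel indices, axis order (x, y, z), physical position
`origin_mm + index * spacing_mm`.  NIfTI I/O encodes this as a diagonal
affine; only axis-aligned volumes are supported.

## Synthetic phantom cohorts

Real ART cohorts pair a planning CT (pCT) with a mid-course adaptive CT
(aCT) of the same patient.  The generator emulates the features of that
pairing that drive the workflow's behavior, not photorealistic anatomy:

* **Structures** are parametric primitives (ellipsoid, tube, box) from a
  catalog of head analogs in the four standard organ-at-risk groups —
  central (spinal-cord tube, brainstem), bony (mandible box, HU ≈ 700),
  glandular (parotid/submandibular ellipsoid pairs), optic (eyes).  Sizes,
  HU statistics and placement ranges are per-structure configuration;
  placement rejects overlaps with a minimum inter-structure gap (default
  4 mm) and retries the whole layout when crowded.  Images are background
  HU (−50) plus per-structure HU plus additive Gaussian noise
  (SD 15 HU).
* **Glandular analogs are two-compartment**: a clearly visible
  parenchymal core (contrast ≈ +60 HU) occupying a *per-subject random
  fraction* (0.45–0.75 of each semi-axis) of the true structure, whose
  outer rim is nearly isodense with background (contrast ≈ +12 HU, below
  the noise SD).  This models gland boundaries on CT, which are partly
  invisible and contoured from patient-specific anatomical knowledge.  It
  is the mechanism that makes continual training pay off (below): the
  core-to-rim ratio cannot be read off the image, so a cohort-trained
  model can only predict an average rim, while a model trained on this
  subject's own planning contours knows the true extent.
* **Anatomy change** (`derive_adaptive`): glandular structures lose a
  configured volume fraction (default 10%, the typical mid-course
  parotid/submandibular shrinkage) via an isotropic rescale of the
  analytic shape about its center by `(1−s)^(1/3)` per axis, then
  re-rasterization.  Non-glandular structures are displaced by a smooth
  random field (shared rigid shift + one low-frequency sinusoidal mode,
  clamped to the 2 mm default amplitude, evaluated at the structure
  center) **snapped to whole voxels**, so their rasterized volume is
  preserved exactly — sub-voxel inter-scan motion is not resolvable on
  the grid anyway.  The adaptive image gets a fresh noise realization.
  Realized glandular shrink is within ±2 percentage points of the request
  when averaged over ≥10 seeds; single small structures can deviate by a
  few percent from rasterization granularity.

What the phantoms do **not** model: soft-tissue texture, CT artifacts,
couch/immobilization hardware, true deformable (non-rigid per-structure)
anatomy change, inter-observer contour variability.  Passing benchmarks on
phantoms therefore demonstrates the *workflow's* correctness and the
*direction* of protocol effects, not clinical-grade accuracy.

## Preprocessing

Resample to a target spacing (clinical default 1.0 × 1.0 × 3.0 mm;
trilinear for images, nearest for masks), crop/pad to a fixed global field
of view (default 320 × 256 × 130 voxels, padded with the low window
bound), window HU [−100, 300] affinely onto [−1, 1] with clamping, and —
for the localization step — block-average downsample (default ×2 in x, y),
masks by majority vote with ties counted foreground.  The crop center
defaults to the grid center; centering on the union bounding box of
provided masks is available.  All steps preserve physical coordinates
through origin bookkeeping.

## Network

A 3D FC-DenseNet (Tiramisu layout): initial convolution, dense blocks
with transitions down (1×1×1 convolution + average pooling), a bottleneck
block, and transitions up (strided transposed convolution, kernel = stride)
with skip concatenation from the matching encoder scale; 1×1×1 head.
Within a block each 3×3×3 layer sees the concatenation of the block input
and all previous layer outputs and emits `growth_rate` channels.
Normalization layers are omitted (batch size 1).  The implementation is a
small numpy reverse-mode autodiff (im2col + BLAS convolutions, analytic
loss gradients, Adam); gradients are verified against central finite
differences in the test suite.

Options that matter at desk scale:

* `append_coords` — three normalized coordinate channels on the input.
  Enabled for the step-1 localizer in the small profiles: without an
  absolute position signal a tiny multiclass network cannot separate
  bilateral classes (left vs right parotid), and their predicted centroids
  collapse toward the midline.  Disabled for step-2 ROI networks, where
  in-box coordinates teach a harmful position-in-box prior that breaks
  when the test-time box is anchored slightly differently than the
  training box.
* Loss — *dual cross entropy*: per-voxel multiclass cross entropy plus a
  weighted second term `−Σ_{bg voxels} Σ_{c≥1} log(1 − p_c)` that
  penalizes confident foreground on background voxels; `fp_weight = 0`
  reduces exactly to plain cross entropy (verified against a direct
  per-voxel computation).  The exact published form of this loss is not
  fully specified in the literature we follow, so the term is exposed as a
  configurable family, with Dice loss and per-channel sigmoid BCE as
  alternatives.  The desk profiles train with `fp_weight = 0`: on heavily
  imbalanced tiny grids the false-positive term suppresses rare-class
  foreground and caused empty localizations.

## Two-step segmentation

1. **Localize**: multiclass segmentation of all structures at once on the
   downsampled FOV; predicted voxel indices are mapped to full-resolution
   index space by multiplying with the downsample factors.
2. **ROI**: each structure's *middle point* is the rounded voxel centroid
   of its predicted coarse voxels (bounding-box center available); a
   preset per-structure box (the `RoiSizeTable`, default = training-label
   bounding-box maxima padded 25% and rounded up to the network's
   divisibility) is centered there and *shifted, not shrunk*, to lie
   inside the grid, so each per-structure network always sees a fixed
   input size.  In addition to the thresholded centroid the localizer
   exposes a probability-weighted anchor (mass above half the class
   maximum); the pipeline prefers it because the centroid of a handful of
   argmax voxels is noisy.  A structure with no prediction is flagged
   missing; fallbacks are the probability anchor, then an optional
   cohort-mean centroid from training labels, then an empty mask with a
   warning.
3. **Segment**: a single-label network per structure on the
   full-resolution windowed crop; optional largest-connected-component
   cleanup (off by default).
4. **Assemble**: box masks pasted back into zeroed full-grid masks;
   provenance records boxes, missing structures and model checksums.

With ground-truth stub networks substituted for both steps the pipeline
reproduces the input labels exactly (DSC = 1.0) — the standing plumbing
test.

## Training protocols

For a cohort with both scans per subject, `allocate_splits` draws disjoint
test / shared-train / extra-train subject sets (sizes requiring
`n_extra = n_test` so the two training sets match in size).  The
**matched** (continual) protocol trains on planning scans of
shared ∪ test subjects; the **unmatched** (conventional) protocol on
shared ∪ extra.  Test evaluation is always on the *adaptive* scans of the
test subjects, which a programmatic audit asserts never enter any training
manifest.  Both protocols start from the same seeded initialization.
`continual_finetune` offers the cheaper operational variant — fine-tuning
the conventional model on one subject's planning scan — returning a tuned
copy and leaving the base model untouched.

## Evaluation metrics

With computer contour C and reference M (voxel counts |·|):
`DSC = 2|C∩M|/(|C|+|M|)`, `FPD = 2|C∖M|/(|C|+|M|)`,
`FND = 2|M∖C|/(|C|+|M|)`; the identity `2·DSC + FPD + FND = 2` holds
exactly and pins the FPD/FND reconstruction.  Surface voxels are
foreground voxels with a 6-connected background (or out-of-grid) neighbor;
directed distances are exact Euclidean distances in mm (distance
transform, verified against an all-pairs brute force to 1e-9 mm).  HD95 is
the 95th percentile of the pooled bidirectional vector — numpy's linear
(R-7) interpolation by default, with Weibull (R-6) and nearest-rank
switchable, since toolkits disagree on this convention.  MSD is half the
sum of the two directed means.  Policy for empty masks: distance metrics
raise; one-sided empties score DSC 0 and are flagged `missing`; both-empty
rows are excluded.

**Statistics**: per structure, paired per-subject differences are screened
with Shapiro–Wilk (α = 0.05); a paired t-test is used when normality is
not rejected, otherwise the Wilcoxon signed-rank test, and the output
records which test fired.  With three methods under comparison, the
Bonferroni threshold is 0.05/3 ≈ 0.0167.  On simulated reports the
procedure detects a +0.1 DSC shift (SD 0.01, n = 20) in >95% of
replicates with a false-positive rate below α.

## Turing-test module

`build_scenarios` produces a blinded, order-randomized, balanced
assignment over three question types (discrimination, pairwise preference,
quality assurance; a *major error* means a subjective difference of more
than 10% of the contour).  The presentation file contains only opaque item
ids — an audit greps it for method names; the truth key is a separate
file.  The default configuration (4 methods × 9 structures × 2 per cell
for single-contour questions, 3 method pairs × 9 × 2 for preferences)
yields 198 scenarios.  Scoring returns judged-human rates with Wilson 95%
intervals, head-to-head preference rates (complementary to 100% per
pair), and no/minor/major revision rates.  Observer-consistency analysis
is deliberately out of scope.

## Desk-scale profiles and benchmark design

Two frozen profiles (`adaptseg.profiles`) drive the benchmarks:

* **smoke** — 8 six-structure phantoms of 64 × 64 × 16 voxels at
  1 × 1 × 3 mm; tiny network (2 transitions, pools (2,2,2)/(2,2,1),
  growth 4, first 8 channels); 45/60 epochs at learning rate 3e-3 (the
  faint-rimmed glandular analogs need roughly the same optimization
  effort here as in the desk profile).  Checks that training loss
  decreases and that a phantom seen in training is segmented with
  DSC > 0.6 per structure (runs in ~3.5 min).
* **desk** — five independent 10-subject cohorts (cord, mandible, parotid
  pair; 48 × 48 × 12 voxels at 1.5 × 1.5 × 4 mm), split 3 test / 4 shared
  / 3 extra, 10% glandular shrink, 45/45 epochs.  Matched vs unmatched
  mean test DSC is compared per replicate (runs in ~10 min).  The split
  uses 3 rather than 2 test subjects to average test-subject noise; the
  proportions still mirror a 20-test/60-train design.

The continual-training comparison is a stochastic, directional benchmark:
the expected result is matched ≥ unmatched in at least 4 of 5 replicates
with the largest per-structure gap on the glandular analogs — the
qualitative pattern of the clinical finding it emulates, not its absolute
numbers, which depend on cohort size and anatomy realism far beyond desk
scale.

## Numerical and degenerate-input choices

* float32 network arithmetic; losses accumulated in float64; probabilities
  clamped to [1e-7, 1−1e-7] inside logarithms.
* Centroid rounding is `floor(x + 0.5)` (half away from zero) for
  determinism across platforms.
* Ties in per-voxel argmax resolve to the lower class index; mask
  downsampling ties count as foreground.
* Training aborts with the epoch named if the loss goes non-finite;
  `epochs = 0` is a supported no-op.
* All randomness flows from explicit integer seeds; identical
  (config, seed) reruns are bit-identical for generation and replay
  identical loss histories for training on the same BLAS.

## Known limitations

* The numpy network trains tiny models well but is not performant at the
  clinical profile's grid size; the clinical defaults document the
  intended configuration rather than a tested runtime.
* Phantom realism is group-level only (size, HU, variability, shrink);
  absolute DSC values on phantoms do not transfer to patients.
* Deformable-registration comparators and dosimetric evaluation are out
  of scope.
* One network per named structure; bilateral organs are not weight-shared.
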