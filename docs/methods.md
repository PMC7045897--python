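# Methods

## Problem setting

The pipeline segments lesions on paired dual-sequence head MRI: a
T1-weighted volume (coarser in-plane resolution, here 0.93 × 0.93 × 4 mm)
and a T2-weighted volume (finer, 0.48 × 0.48 × 4 mm) of the same anatomy,
with an expert binary gold-standard mask drawn on the T2W grid (1 inside
the lesion, 0 elsewhere). The two sequences carry complementary
information: part of a lesion can be hypointense (background-like) on T1W,
while T2W shows the full lesion but also bright non-lesion structures that
a single-sequence model confuses with tumor. Segmentation is 2D per axial
slice; detection, training and evaluation are organized per patient.

## Synthetic phantom generator

Clinical dual-sequence cohorts with gold masks are rarely shareable, so
`deuseg.phantom` generates the statistical structure the pipeline assumes:

* **Scene.** Axis-aligned ellipsoidal lesions with per-axis radii drawn
  uniformly from `lesion_radius_range` (default 5–10 mm), placed uniformly
  so they never cross the volume boundary (a lesion that cannot fit raises
  an error naming the offending axis). Ellipsoids are evaluated
  analytically at voxel centers, so the discretized mask is exactly
  reproducible by an independent voxel-center-inside-ellipsoid scan.
* **Channel contrast.** Channel 2 renders the full lesion at
  `lesion_level_ch2` (default 0.9 vs background 0.2) plus
  `confuser_count` bright non-lesion ellipsoids (default 3, radii 4–7 mm)
  disjoint from every lesion. Channel 1 renders the lesion at
  `lesion_level_ch1` (0.8) *except* a connected sub-region covering
  `t1_hypointense_fraction` of its volume (default 0.5), left at
  background level. The sub-region is a half-space cut through the
  ellipsoid; the cut offset comes from exact spherical-cap geometry in the
  ellipsoid's unit-sphere coordinates, so the targeted volume fraction is
  analytic. With these defaults neither channel alone determines the
  lesion support — the construction the dual-input comparison relies on.
* **Grids and misalignment.** The channel-2 grid is `grid_shape` at
  `spacing_ch2`; channel 1 covers the same physical extent at its own
  coarser `spacing_ch1`, sampled at coordinates shifted by
  `misregistration_offset` (default 2 mm in-plane) to emulate residual
  inter-sequence misalignment. Declared origins are voxel centers, so the
  only inconsistency between the channels is the planted offset.
* **Noise.** Additive Gaussian noise (sd 0.02) clipped to non-negative,
  drawn independently per channel. No MRI physics (bias fields, k-space
  artifacts) is simulated, and lesions are smooth ellipsoids rather than
  the irregular shapes of real tumors — passing tests therefore establish
  correctness of the machinery, not clinical performance.

Identical seeds give bit-identical phantoms.

## Preprocessing

Fixed order: **register → resample → normalize → pad/crop**; masks always
travel through the same geometric operators as images, with
nearest-neighbour interpolation so binarity and voxel correspondence are
exact (a strict mode with linear interpolation + 0.5 re-binarization is
available behind a flag).

* **Registration** (channel 1 → channel 2 grid): Mattes mutual information
  (50 bins) optimized by a (1+1) evolutionary strategy, initial search
  radius 0.004, at most 300 iterations per level, rigid
  (translation + rotation) by default with affine selectable. Three
  implementation choices stabilize the search: a coarse-to-fine pyramid
  (shrink 4/2/1, dropping levels that would leave fewer than 4 voxels
  along any axis); explicit parameter scales mapping the initial radius to
  about 1 mm translation steps while damping rotations (same-session
  intra-patient misalignment is translation-dominated); and residual
  Gaussian smoothing (0.75 voxel) at the finest level, which suppresses
  the known off-grid MI interpolation artifact on near-piecewise-constant
  images. The optimizer's RNG is fixed, and if the optimized metric is
  worse than at the initial centered transform the initial transform is
  kept, so registration never worsens alignment. Non-overlapping physical
  extents raise an error.
* **Resampling**: in-plane rows/cols halved (floor division on odd sizes);
  output voxel `j` samples input coordinate `2j + 0.5` (aligned voxel
  centers), linear for images, nearest-neighbour for masks. Spacing
  doubles, slice count unchanged.
* **Normalization**: min-max per volume onto [0, 1]; a constant volume
  maps to all zeros by convention.
* **Pad/crop**: symmetric zero padding and centered cropping to the
  network input size; the applied index offset is returned so images and
  masks shift identically. The operation is idempotent at a fixed target.

## Network

`DEUConfig` fixes the architecture; all width claims are config-relative.
Defaults: input 256 × 256, stage widths (32, 64, 128, 256), growth rate
K = 32 with 4 dense micro-blocks, group-norm groups 8 (validated
divisibility for every normalized width), leaky-ReLU slope 0.1, group-norm
epsilon 1e-5, He-uniform initialization from a recorded seed.

* **Encoder block**: three 3 × 3 convolutions; GN + LReLU after the first
  two; the third at stride 2 halves the spatial size. The features before
  the stride-2 convolution are the decoder skip source.
* **Dense connectivity block**: micro-blocks of
  GN–LReLU–conv 1×1 (bottleneck 4K)–GN–LReLU–conv 3×3 (K channels); each
  micro-block receives the concatenation of the block input and all
  previous outputs, so the pre-transition width is `w_in + m·K`. The
  transition (GN → 1 × 1 convolution → 2 × 2 average pooling) compresses
  back to `w_in` and halves the spatial size.
* **Topology**: with dual input, two independent first-stage encoder
  blocks (one per sequence) are concatenated channel-wise and fused in the
  dense block; three further encoder blocks follow; five decoder blocks
  (3 × 3 transposed convolution doubling the size, skip concatenation, two
  3 × 3 conv + GN + LReLU refinements at stride 1) mirror the five
  downsamplings (four encoder stages + the transition pooling); a 1 × 1
  convolution with pixel-wise sigmoid produces the probability map, which
  therefore has exactly the input size. The single-sequence variant has
  one first-stage path feeding the dense block directly and is otherwise
  identical (a strict sub-model, with strictly fewer parameters).
* **Reconciliations.** The five-decoder layout requires five total
  downsamplings, which fixes three (not two) post-dense encoder stages;
  and the decoder's refinement convolutions run at stride 1, since stride
  2 there would contradict reconstruction to the input size. Skip sources,
  "same" zero padding, the 4K bottleneck width, and transition
  compression back to the dense input width are likewise design choices
  where the architecture description leaves freedom; each is overridable
  through `DEUConfig`.

The layer library is a minimal numpy implementation (im2col/col2im
convolutions; transposed convolution as the exact adjoint of a strided
convolution, so the pair is gradient-consistent by construction), verified
by central-difference gradient checks down to 1e-6. Forward runs in
float32; gradients accumulate and backpropagate in float64, because
group-norm backprop through near-constant activations (e.g. empty
background slices) amplifies by `1/sqrt(var + eps)` per layer and can
exceed the float32 range — Adam's per-parameter normalization makes large
finite gradients harmless, while float32 overflow would poison the
weights.

## Training

Soft Dice loss `1 − (2Σpg + s)/(Σp + Σg + s)` with smoothing s = 1
(required so empty-mask slices, which are kept in training, contribute a
finite gradient), Adam (lr 1e-4, β₁ = 0.9, β₂ = 0.999, ε = 1e-8), batch
size 1, 200 epochs by default, final-epoch weights (no checkpoint
selection, no schedule, no early stopping). Augmentation per sample and
epoch: horizontal flip with probability 0.5 and spatial rescale by a
factor in [0.9, 1.1] followed by pad/crop back, applied identically to
both channels and the mask (nearest-neighbour for the mask). All
randomness — shuffling, augmentation, initialization — derives from the
configured seed; two runs with the same seed produce identical loss
curves.

## Post-processing and evaluation

Per patient, slice probabilities are stacked into a 3D volume, thresholded
at 0.5 (ties to foreground), labeled into 3D connected components
(26-connectivity by default; 6 and 18 selectable since the choice changes
component counts), and components confined to a single axial slice are
removed as isolated false positives. The operation never adds voxels and
is idempotent. No other morphology (hole filling, size filtering) is
applied.

Metrics are computed on the pooled 3D volume per patient. Conventions for
degenerate cases: DSC of two empty masks is 1 (logged); sensitivity with
empty gold and precision with empty prediction are reported as missing
(NaN), never as 0. Cross-validation partitions patients with a shuffled,
seeded, balanced k-fold (fold sizes differ by at most one; every patient
tested exactly once). The input comparison trains T1W-only, T2W-only and
dual models under identical folds and seeds, reports mean ± sd per metric
(sd both over folds and over patients, since either aggregation is
defensible), and compares per-fold DSC with a two-sided Mann-Whitney U
test (exact null distribution for tie-free samples of ≤ 8, tie-corrected
normal approximation otherwise; U reported under the min convention).

## Problem sizes in the tests and acceptance script

CPU-scale stand-ins are used throughout: phantoms of 12 slices at 64 × 64
(channel 2) preprocessed to 32 × 32 inputs; networks with stage widths
(4, 8, 8, 8) or (8, 16, 16, 16); 12-patient cohorts with 2-fold
cross-validation over 3 seeds for the dual-vs-single comparison; a
learning rate of 1e-3 for these tiny fixtures (the 1e-4 default is tuned
for full-scale runs and converges too slowly for hundred-step budgets).
The directional claim — dual-input mean DSC at least matching each
single-input mean — is the scale-independent property checked; absolute
DSC values at this scale are not comparable to clinical-resolution
results.

## Known limitations

* The phantom's intensity levels are free parameters, not calibrated to
  any clinical cohort; no intensity statistics of real tumors are
  emulated.
* 2D slice-wise segmentation with 3D cleanup only; no 3D convolutions.
* Registration assumes rigid (or affine) motion and overlapping extents;
  no deformable registration.
* The numpy backend is single-threaded BLAS-bound; full-resolution
  (256 × 256) training is feasible but slow — the package's tested regime
  is the reduced scale above.
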