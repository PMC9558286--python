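# Methods

This note documents the models implemented in `t1synth`, the choices made
where the design was open, and what the phantom experiments do and do not
demonstrate.

## Problem setting

Monitoring disease activity in multiple sclerosis rests on finding *new*
T2 lesions between a baseline and a follow-up MRI scan. Detection models
work best with two contrasts (T2-FLAIR plus T1-weighted), but a T1
acquisition is not always available. The package implements a two-stage
answer: (1) synthesize a T1-weighted volume from the FLAIR volume with a
cluster-conditioned 3D adversarial network, and (2) feed the synthetic T1
(T1S) alongside the FLAIR into a longitudinal new-lesion detector that
jointly learns deformable registration and segmentation. An evaluation
suite scores synthesis quality (global SSIM, median absolute error) and
lesion-wise detection (sensitivity, FDR, precision under the
one-voxel-overlap rule; paired two-sided Wilcoxon signed-rank tests across
model variants).

## Synthesis model

**Conditioning.** The FLAIR volume is hard-clustered into `c` intensity
classes (Gaussian-mixture EM on in-brain intensities, seeded k-means++
initialization, best of 5 restarts; optional mode-filter spatial
smoothing). Labels are re-indexed by ascending cluster mean so channel
semantics are stable across images (channel 0 = darkest tissue). `c = 3`
maps onto CSF/GM/WM; `c = 5` adds the two partial-volume shells; `c = 7`
and `9` are finer intensity quantizations without a one-to-one biological
reading. The one-hot stack of the cluster map is the generator input. A
plug-in accepts an externally computed label map (e.g. from FSL FAST) in
place of the built-in clustering. Hard labels are used rather than
per-class probability maps; the probability variant exists behind
`from_label_volume` but is untested against any reference.

**Generator.** A patchwise (32³) residual U-Net of 8 residual blocks —
4 encoder + 4 decoder around a bottleneck, the only split compatible with
32³ patches and 2× pooling. Each block is two 3×3×3 convolutions with
batch normalization; downsampling is a stride-2 2×2×2 convolution;
upsampling its transpose; skip connections merge by voxelwise **summation**
(1×1×1 projection where widths differ), and the head is a 1×1×1
convolution with a sigmoid, so outputs live in [0, 1].

**Discriminator.** A 4-block residual network on 32³ patches, each block
followed by stride-2 pooling, global average pooling and a linear head
giving one real/fake logit per patch. It is unconditional (sees only T1
patches); a conditional variant would concatenate the cluster channels but
is not implemented.

**Training.** Alternating Adam updates. Discriminator: binary
cross-entropy with one-sided label smoothing — real patches target
1 − ε (ε = 0.1 by default), generated patches target 0. Generator:
`adv_weight` × (fool-the-discriminator BCE) + `l1_weight` × mean absolute
voxel error against the real T1 patch. The default weight ratio is 100:1
(L1:adversarial), the pix2pix convention; with `adv_weight = 0` training
reduces to pure voxelwise regression and no discriminator is built.
Patches are drawn from a stride-16 lattice (exhaustive by default, random
sampling available via `patches_per_volume`), keeping only patches with
≥ 5 % brain voxels.

**Whole-volume inference.** 32³ patches at stride 16; overlapping
predictions are blended with a separable Hann window plus a small floor,
normalized by the accumulated weight so the blending is a partition of
unity (a constant field reassembles exactly; patch-seam intensity
artifacts are suppressed). Output is masked to the brain and clipped to
[0, 1].

## Detection model

Per input modality a 3-level U-Net (two downsamplings) maps the
(baseline, follow-up) patch pair to a dense displacement field in voxel
units; its head is zero-initialized so training starts from the identity
warp. The baseline patch is warped by trilinear interpolation —
differentiably, so segmentation gradients flow back through the warp into
the registration network. The warped baselines and follow-ups of all
modalities are concatenated into a second 3-level U-Net with a 2-class
softmax output.

The loss is the sum over modalities of an unsupervised registration term —
masked MSE between warped baseline and follow-up, plus λ × the mean over
voxels of the summed squared forward differences of each displacement
channel (λ = 1 by default; for a linear field d_c(v) = αv_c the penalty
evaluates to 3α², a closed form used as a unit test) — plus a voxelwise
weighted cross-entropy against the new-lesion mask. Adam optimizes
everything end-to-end. "Gradient descent vs Adam": both appear in the
source description of this family of models; Adam is used here for all
parameters.

**Sampling and class balance.** Training patches come from the 32³ /
stride-16 lattice; patches containing lesion voxels are oversampled to
half of each batch (with the default batch size of 1 this degenerates to
alternating lesion/background patches), and lesion voxels receive a fixed
cross-entropy class weight (default 35; `0` switches to inverse-frequency
capped at 200). Without both measures the positive class — a few tens of
voxels per 64³ phantom — is starved at desk scale. The default 300 Adam
steps matter qualitatively: sensitivity saturates within ~150 steps but
false-positive suppression emerges only in the later phase of training.

**Inference rules.** Tiled stride-16 Hann-blended probability maps;
voxels with probability ≥ 0.5 (inclusive) are lesion candidates; a lesion
must have at least 3 voxels under 26-connectivity ("a minimum of three
neighboring voxels" is read as component size ≥ 3, the standard
lesion-analysis interpretation that matches how TP/FP counting operates).
An alternative threshold of 0.3 is exposed for operating-point analysis.

## Preprocessing

Mono-modal affine registration (translation / rigid / full affine)
maximizing masked negative MSE by coarse-to-fine Powell search at
downsampling factors (4, 2); with unit-spacing 64³ phantoms the omitted
full-resolution level changes the objective by < 10 % while cutting the
cost ~5×, and simulated-shift recovery stays well under half a voxel. The
follow-up image gets one transform to the reference grid; the baseline
gets the *composition* baseline→follow-up→reference, so it is interpolated
once. For phantoms the follow-up grid itself acts as the reference
("template") space; real-data users supply any template volume.

Skull stripping: Gaussian-smoothed (σ = 2) three-class Otsu, lowest
threshold backed off by 0.6 toward air (CSF and background noise overlap
in FLAIR), largest 26-connected component, morphological closing and hole
filling. This is a deliberately simple mask generator with a plug-in
contract: any precomputed mask is accepted verbatim. Intensity
normalization maps the 1st–99th in-mask percentiles to [0, 1] with
clipping; percentile-clipped min-max is outlier-robust where raw min-max
is not, and the percentiles are configurable.

## Phantom generator

The phantom emulates exactly the features the pipeline exercises, and no
more. Anatomy: concentric deformed-ellipsoid shells (CSF outermost, then
GM, WM innermost; semiaxes 0.42/0.40/0.38 of the grid, radial coordinate
perturbed by a smooth random field) with one-voxel partial-volume labels at
the two tissue interfaces — the c = 5 clustering finds precisely these
shells. Default contrasts (arbitrary units in [0, 1]): FLAIR — CSF 0.10,
GM 0.60, WM 0.45, lesion 0.90 (hyperintense); T1 — CSF 0.10, GM 0.45,
WM 0.75, lesion 0.35 (hypointense, GM/WM contrast inverted vs FLAIR).
Rendering multiplies class means by a smooth multiplicative bias field
(peak-to-peak 0.2) and adds Gaussian noise (σ = 0.03), clipped at 0.

A longitudinal case inserts 1–3 spherical new lesions (radius 1.5–3
voxels, so every component has ≥ 19 ≥ 3 voxels) strictly inside follow-up
WM, renders both contrasts at both timepoints, and pushes the baseline
volumes through a random small rigid misalignment (±3 voxels, ±3°) — the
residual the preprocessing and the detector's registration sub-network
must undo. Stable patients are emulated by a zero-lesion spec. All
randomness flows from explicit seeds.

What the phantom does **not** model: MR relaxometry, multi-scanner
contrast variation, anatomy beyond three shells (no cortical folding,
ventricle geometry, vasculature), pre-existing (non-new) lesions, atrophy
or any non-lesion longitudinal change. Passing phantom tests therefore
demonstrates that the mechanisms work — clustering recovers the intensity
classes, synthesis learns the cross-contrast mapping, the detector learns
registration + change detection end-to-end, the metrics are correct — not
that clinical performance figures transfer.

## Desk-scale defaults

All networks run on a single CPU through a small numpy engine
(im2col-lowered convolutions into BLAS matmuls, hand-written backward
passes verified against finite differences; a shared scratch-buffer pool
bounds peak memory). Problem sizes are chosen for that regime: 64³
phantoms, width-4 generator (width-8 detector), 300 Adam steps at batch size 1
(≈ 0.7 s/step for a two-modality detector; a three-arm phantom experiment
runs in under 15 minutes). These defaults are the
package's study conditions for its own experiments; larger widths, steps
and volumes are plain configuration changes.

## Numerical notes

* Determinism: every stochastic stage takes an explicit seed; reruns are
  bit-identical (scores files hash-equal). Model files round-trip to
  bit-identical inference.
* Cluster count c must not exceed the number of distinct in-mask
  intensities; EM components get a variance floor (`reg_covar = 1e-8`);
  coincident sorted means raise rather than silently merging. The mixture
  is fit on a seeded 30 000-voxel subsample (assignment covers every
  voxel); a 1-D mixture is estimated to ample precision from that many
  samples at a fraction of the cost.
* SSIM is computed **globally** over the brain mask from single means,
  standard deviations and covariance (a windowed variant exists behind a
  flag for cross-checks only). Stabilizers default to c1 = (0.01 L)²,
  c2 = (0.03 L)², c3 = c2/2 with L = 1.
* Undefined ratios (0/0 — e.g. sensitivity on a stable case) propagate as
  NaN, never as silent zeros, and are dropped pairwise from Wilcoxon
  comparisons; summary tables report both drop-undefined and zero-fill
  aggregations.
* The Wilcoxon signed-rank test drops zero differences, uses the exact
  null for ≤ 25 remaining pairs and the tie-corrected normal approximation
  beyond; it requires ≥ 6 defined pairs — pairwise arm tables on smaller
  test sets mark the p-value undefined rather than extrapolating.
* Out-of-field voxels in any resampling are 0; label images always use
  nearest-neighbour interpolation.

## Known limitations

* The built-in skull stripper is calibrated for phantom-like
  foreground/background statistics; real scans should supply an external
  mask through the plug-in contract.
* The adversarial term at desk scale mostly regularizes texture; with tiny
  widths and steps the L1 term dominates, which is why the overfit tests
  gate on the regression configuration.
* Per-batch inverse-frequency class weighting makes the loss scale depend
  on batch composition; the fixed default avoids this but is a tuning
  constant, not a law.
* The three-arm comparison on phantoms checks mechanism only; phantom
  lesion contrast is deliberately strong, so absolute sensitivities are
  higher and arm orderings need not match clinical data.
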