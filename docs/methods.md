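# Methods

`vessel3d` reconstructs a 3D model of blood vessels from an ordered stack of
stained serial tissue sections and analyses its branching. This note
documents the models and procedures the package implements, the defaults it
ships, the synthetic data it is validated on, and the numerical choices a
user should know about.

## Problem setting

A tissue block is cut into consecutive sections a few micrometres thick
(4 µm for H&E-stained material, 3 µm for CD31/DAB in the geometry we
emulate), each mounted and scanned independently at 0.28 µm/pixel. Three
obstacles separate these images from a 3D model: vessels must be segmented
in each section; the sections must be brought into one coordinate system
(each carries an independent rigid/affine mounting error plus a smooth
tissue deformation); and the aligned binary masks — ~14× coarser along z
than in-plane — must be interpolated into a near-isotropic volume before
skeleton analysis.

## Segmentation

Two segmenters share one interface:

* **Block-based Otsu** (`otsu_block_segment`): the luminance image
  (0.299 R + 0.587 G + 0.114 B) is tiled into blocks (default 64 px) and each
  block is thresholded at the value maximizing between-class variance of its
  8-bit histogram. Blocks whose dynamic range falls below `min_contrast`
  (default 10 grey levels) contain one class and are marked background.
  Whether vessels are the darker or brighter class is a polarity flag;
  the default (darker) matches hematoxylin- and DAB-stained vessels on
  luminance. Thresholds use the smallest argmax, so ties break low.
* **U-net** (`train_unet` / `predict_mask`): an encoder–decoder with skip
  connections and a two-class softmax head, trained on ground-truth patches
  (default 224×224, split 70/30 into training/validation) with AdamW, a
  one-cycle learning-rate schedule (peak 3e-3 by default) and cross-entropy
  loss. Training stops early once the validation dice reaches a target
  (default 90%) and always returns the best-validation checkpoint.
  Validation dice is pooled over all validation-patch pixels (a per-sample
  dice) rather than averaged per patch: the random 70/30 patch split does
  not tile complete slices, so a slice-wise dice is not computable at
  validation time. Inference tiles the full image with half-patch overlap
  and blends class probabilities before the argmax.

The network layers (stride-1 convolutions with manual backpropagation,
2× max-pool / nearest upsample, AdamW, one-cycle schedule) are implemented
in numpy in `vessel3d.nn`; the same toolkit powers the registration flow
network. The architecture is deliberately compact (default 8 base channels,
2 pooling levels): the class structure of stained sections is chromatic
rather than semantic, and a small network keeps CPU training in minutes.
Depth/width, epochs and batch size are exposed in `SegConfig`.
With cross-entropy and a ~10% foreground fraction, the first ~100 optimizer
steps typically sit in an all-background plateau before the loss separates
the classes; budgets below that (very few patches or epochs) will return a
collapsed segmenter.

## Coarse registration

Consecutive sections are aligned pairwise with a 6-parameter affine
(translation, rotation, log-scales, shear) acting about the image centre,
by maximizing mutual information (MI) of the joint intensity histogram —
robust to the stain-intensity differences between sections. The search is
hierarchical: a Gaussian pyramid (default 3 levels, coarsest ≥ 32 px) with a
bounded derivative-free Powell minimization of the Parzen-smoothed negative
MI at each level (48 bins, 1-bin Gaussian smoothing), translations doubled
at each descent, and a second Powell pass at full resolution to refresh the
direction set. Parameters are internally rescaled so one optimizer unit
perturbs the objective comparably for every degree of freedom. Several
numerical points matter:

* Pixels that sample outside the moving frame are excluded from the
  histogram. Including them (as zeros) biases the optimum toward shrinking
  the moving image into its own border — with the exclusion, recovery error
  on synthetic pairs drops roughly tenfold.
* The objective is MI *weighted by the overlap fraction* (the total shared
  information). Per-pixel MI over the valid region alone rises as the
  overlap shrinks, which rewards absurd translations once the search range
  is wide enough to find them.
* The search is seeded globally at the coarsest level: phase correlation
  over a fan of candidate rotations (±20°, the relative rotation of two
  independently mounted sections can be twice the per-slice maximum) plus a
  dense translation grid, arbitrated by the MI objective. A wrong rigid
  basin at the coarsest level would otherwise poison every finer level and,
  through chaining, every downstream slice. Translation bounds likewise
  span twice the per-slice maximum.
* If the optimized MI at full resolution is below the MI at identity, the
  identity is returned with `converged=False`; chaining then degrades
  gracefully instead of propagating a bad link.

Pairwise transforms are chained into the frame of slice 0 (the anchor is
arbitrary; 0 is the documented choice) by matrix composition; slices before
a non-zero reference use inverses. An optional rectangular ROI can restrict
the objective when surrounding tissue would dominate the histogram.

## Deformable finetuning

Residual smooth deformations are removed by a flow field per consecutive
pair, predicted by one compact U-net (2-channel input: moving and fixed;
2-channel output: row/col displacement) shared across all pairs of a stack
and trained unsupervised. The loss per pair is bidirectional: local
normalized cross-correlation (NCC) between the forward-warped moving image
and the fixed image, plus NCC between the backward-warped fixed image and
the moving image, plus λ times a flow-gradient penalty on both flows.
Local NCC uses uniform windows (default 9 px) evaluated over fully-interior
window positions; the loss is `1 − mean NCC ∈ [0, 2]` with an
ε-regularized (1e-10) variance so constant windows contribute 0 rather than
a blow-up. The gradient penalty is the sum over axes of the mean squared
forward difference of both displacement components — 0 iff the flow is
constant, exactly 1 for a unit ramp. Both losses are backpropagated
analytically through the bilinear warp (the spatial-transformer derivative
of sampling position), verified against numerical differentiation in the
test suite.

Defaults: window 9, λ = 1 (λ = 2 measurably over-smooths on the synthetic
stacks; λ = 0.5–1 behaves equivalently), AdamW with one-cycle peak 3e-3,
60 epochs over all pairs. The final 1×1 head is initialized near zero
(σ = 1e-3) so training starts at (almost) the identity warp while still
passing gradient into the encoder — an exactly-zero head would block all
upstream gradient. `train_scale` optionally trains and predicts at reduced
resolution (flows are upsampled and rescaled); `flow_smooth_px` optionally
Gaussian-smooths the predicted flow, suppressing noise-driven local warps.

Two safeguards keep the unsupervised flows honest:

* **Bounded displacement.** The raw network output is squashed through
  `a·tanh(·/a)` with `a = max_flow_px` (default 6 px, ≈3× the RMS mounting
  deformation expected at this resolution; `None` disables). Consecutive
  sections differ in *content*, not only in alignment, and an unbounded
  NCC optimum happily deforms one section's anatomy onto its neighbour's;
  those warps then propagate down the chain. The squash is differentiable,
  so training itself optimizes within the bound.
* **Single-resample mask alignment.** Masks are warped by the composed
  affine-plus-flow map in one interpolation pass
  (`warp_affine_then_flow`); re-binarizing twice measurably erodes
  one-or-two-pixel-wide vessel rims.

Applied flows are backward-sampling (each output pixel pulls from the
moving image). Per-slice flows toward the reference are built in chain
order and composed by resampling
(`F_i(p) = F_{i-1}(p) + f_i(p + F_{i-1}(p))`), mirroring the affine
chaining. The validated study settings for the synthetic experiments use
window 13, `flow_smooth_px = 2`, `train_scale = 0.5` and 200 epochs.

## Reconstruction

Aligned masks are stacked in cutting order (first section at z = 0) and
`k − 1` intermediate planes are inserted per gap, `k = round(thickness /
pixel)` (k = 14 for the 4 µm / 0.28 µm geometry), each the per-pixel linear
blend of the two bounding binary planes re-binarized at 0.5 — the simplest
faithful definition of bilinear inter-slice interpolation on binary data;
at the exact midpoint the ≥ 0.5 convention keeps both planes' foreground.
The result is a near-isotropic binary volume (z spacing `thickness/k`).
26-connected components smaller than `min_voxels` (default 64) are removed.
Volumes export to NIfTI (spacing in the header zooms, micron units) or
multi-page TIFF (resolution tags + JSON description) and round-trip
bit-identically.

## Skeletonization and branch analysis

Thinning removes *simple* border voxels — deletion changes neither the
number of 26-connected foreground components nor the number of 6-connected
background components in the 3×3×3 neighbourhood (the standard
digital-topology test for the (26, 6) adjacency pair) — protecting
endpoints (exactly one foreground neighbour) and cycling through the six
border directions until a fixed point. Deletion is sequential with
re-checking, which makes topology preservation unconditional and the result
deterministic; neighbourhood verdicts are memoized on the 27-bit pattern.
A cross-check against the scikit-image 3D thinning routine on a cylinder
phantom is part of the test suite; the native implementation is the default
path.

The skeleton condenses into a branch multigraph: voxels of 26-neighbourhood
degree 1 (endpoints) or ≥ 3 (junctions) are nodes; mutually adjacent
junction voxels — the small cliques orthogonal branches form where they
meet — merge into one junction cluster represented by its medoid, so branch
lengths are measured from the junction centre; edges are traced through
degree-2 chains with physical length Σ√((Δz·sz)² + (Δy·sy)² + (Δx·sx)²).
Pure cycles (a ring with no junction) get an anchor node with a self-loop.
The **main branch** of a component is its longest endpoint-to-endpoint
path: exact on acyclic components (the unique tree path, equal to
brute-force enumeration), exhaustive simple-path search on cyclic
components up to an endpoint budget (default 12), and a double-sweep
Dijkstra heuristic beyond it. All remaining edges are sub-branches.
Cycle counts for topology checks are computed independently of the graph,
as components minus the Euler characteristic of the union of closed unit
cubes (the 26-connectivity foreground complex).

## Evaluation metrics

* **Dice** `2|X∩Y| / (|X|+|Y|) × 100`: 100 iff identical, 0 iff disjoint;
  two empty masks score 100 by convention (logged).
* **Mutual dice** `n|X1∩…∩Xn| / Σ|Xi| × 100` over a whole stack: collapses
  to 0 as soon as one slice misses the common overlap, making it a strict
  whole-sequence alignment score. It is permutation-invariant and never
  exceeds the minimum pairwise dice. A union-denominator variant of both
  formulas is available behind `legacy=True` for comparison; it scores
  identical masks at 200 (pairwise) and is not used for reporting. A
  windowed variant (`mutual_dice_windowed`) evaluates overlapped batches of
  consecutive masks for long stacks in which vessels legitimately drift out
  of frame.
* **SSIM** via scikit-image (uniform 7-px window, K1 = 0.01, K2 = 0.03,
  data range 255) on luminance.
* The **registration report** emits, per stage (original / coarse / fine),
  one row per consecutive pair (SSIM %, dice % on ground-truth masks,
  dice % on predicted masks) and one full-sequence row holding the average
  pairwise SSIM and the mutual dice of the stack. "Full-sequence SSIM" is
  defined as the mean of consecutive-pair SSIMs. Negative SSIM is clipped
  to 0 for reporting, with a warning.

## Synthetic phantoms

Because validating the pipeline requires ground truth that real serial
sections cannot provide, `vessel3d.synthetic` generates the full study:

* **Phantom**: branching tubes in a 1 µm voxel grid (default 29×96×96,
  i.e. a 28 µm deep block), each a bounded-curvature random-walk centerline
  (curvature 0.03 rad/step) dilated to its radius (3–6 µm) via the
  distance transform. Trunks start on the top cut face, are biased along
  the cutting axis, and are seeded near the in-plane centre — the ROI is
  chosen around vasculature, as a pathologist crops it; vessels that
  wander laterally faster than their diameter would make the full-stack
  overlap (mutual dice) structurally zero even for perfect alignment.
  Draws are rejected (deterministically) until the centerline graph is a
  clean tree per tube, so endpoint/junction counts are exact.
* **Sectioning**: planes every `thickness_um` (z-interpolated), resampled
  in-plane to `pixel_um`; `floor(depth/thickness) + 1` sections — 8 for the
  default 28 µm / 4 µm geometry.
* **Rendering**: vessel and background pixels around distinct stain-like
  mean colours (H&E: purple on pink; DAB: brown on pale counterstain), soft
  vessel edges, a slow multiplicative illumination field (±8%),
  mid-frequency texture, and i.i.d. pixel noise (σ = 5% of range).
* **Misalignment**: per slice, an independent affine (rotation ≤ 10°,
  translation ≤ 5% width, shear ≤ 0.02, scale deviation ≤ 2%) followed by a
  Gaussian-smoothed white-noise elastic field (RMS 2 px, correlation length
  16 px), applied identically to image and mask, all transforms recorded.
  A centred ROI crop *after* perturbing emulates cropping a fixed window
  out of independently scanned slides, so misaligned content fills the
  frame instead of leaving black borders.

What the phantoms do **not** model: nuclei and stromal morphology, stain
variability between sections, scanner optics, tissue tears and folds, and
vessels entering/leaving the lateral field of view. Passing tests therefore
demonstrate that the algorithms recover known geometry and known transforms
under realistic noise and anisotropy — not that the trained networks
transfer to real histology without retraining.

## Problem sizes used in validation

The test suite and the acceptance script run the study at desk scale,
chosen so the full suite completes on one CPU: 8 sections, 128–224 px ROI
crops, the reduced U-net above, and flow training at `train_scale = 0.5`
on 128 px crops. Section geometry (4 µm / 0.28 µm / 8 sections), the
misalignment magnitudes and the noise level are the study conditions and
are never reduced.

## Known limitations

* The deformable stage shares one small network across a stack; strongly
  slice-specific deformations would need per-pair optimization or a larger
  model.
* Mutual dice of a perfectly aligned stack is bounded by true anatomical
  drift; registration that aligns adjacent *content* can legitimately
  exceed that bound by straightening the anatomy.
* The main-branch definition (longest endpoint geodesic) is exact only up
  to the endpoint budget on cyclic components.
* MI registration assumes overlapping content dominates the histogram; very
  small ROIs or empty sections should use the ROI rectangle option.
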