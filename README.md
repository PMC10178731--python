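# vessel3d

**3D reconstruction and branching analysis of blood vessels from serial
histological sections.**

Angiogenesis — the growth of new blood vessels from existing vasculature —
is studied on stained serial sections of tissue (H&E, CD31/DAB), but each
section is a 2D snapshot: mounted, stained and scanned independently, a few
micrometres from its neighbours, and misaligned by an arbitrary rigid error
plus a smooth tissue deformation. `vessel3d` turns such a stack into a 3D
vascular model and quantifies its branching. It is aimed at image-analysis
researchers and pathology groups who want a scriptable, fully testable
pipeline rather than an interactive tool.

The pipeline:

1. **Segmentation** — per-section vessel masks from a U-net trained on
   expert annotations (patched 224×224, 70/30 train/validation split,
   AdamW + one-cycle schedule, cross-entropy), with a block-based Otsu
   threshold as the classical baseline.
2. **Coarse registration** — consecutive sections aligned by a 6-parameter
   affine maximizing mutual information over an image pyramid; pairwise
   transforms chained into the frame of slice 0.
3. **Deformable finetuning** — a convolutional flow network (spatial-
   transformer style) trained unsupervised on all consecutive pairs with a
   bidirectional local-NCC loss plus a flow-gradient smoothness penalty;
   the learned flows are applied to images and masks.
4. **Reconstruction** — aligned masks interpolated to near-isotropic voxels
   (`k = round(thickness/pixel)` blended planes per gap; 14 for 4 µm
   sections at 0.28 µm/pixel), small objects filtered, volume exported to
   NIfTI/TIFF.
5. **Skeleton analysis** — topology-preserving 3D thinning, a branch graph
   with junction clustering, and per-vessel statistics: main-branch length
   (longest endpoint-to-endpoint path) and sub-branch count/lengths.
6. **Evaluation** — pairwise dice and SSIM, and the sequence-wide *mutual
   dice* `n|X1∩…∩Xn|/Σ|Xi|`, reported per stage
   (original / coarse / fine).

Real serial-section studies rarely ship with usable ground truth, so the
package includes a synthetic module that generates the whole experiment —
3D branching-tube phantoms, physical sectioning (4 µm / 0.28 µm per pixel),
stain-like rendering, and recorded per-slice misalignment — giving every
stage an exact reference. See `docs/methods.md` for models, defaults and
limitations.

## Worked example

`examples/03_register_stack.py` misaligns a rendered 8-section phantom
study and registers it coarse-to-fine:

```text
mutual dice, misaligned stack: 0.0%
mutual dice after coarse (MI affine): 15.4%
mutual dice after fine (flow field): 32.5%
pairwise dice after fine: 94 84 95 87 90 77 82
```

Mutual dice is the overlap common to *all eight* sections at once — near
zero while the stack is misaligned, and recovering sharply once the
sections share one coordinate system; the remaining gap to 100 is the true
anatomical drift of the vessels through the block. The other examples cover
phantom simulation, segmentation (U-net vs Otsu), reconstruction plus
branch statistics, and the one-config full pipeline.

A thin CLI wraps the same functions:

```bash
vessel3d simulate --out study --seed 0
vessel3d run-all config.yaml
vessel3d skeletonize volume.nii.gz --out-table branches.csv
```

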