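# Methods

`cpseg` implements an automatic segmentation pipeline for the fetal
cortical plate (CP) in reconstructed T2-weighted MRI volumes, together
with the evaluation and morphometry stack needed to judge it. Because
clinical fetal MRI cannot be redistributed, the package ships a synthetic
phantom generator that reproduces the geometric and statistical structure
the method relies on; every stage is exercisable end to end on phantoms.

## Segmentation model

One 2D U-Net-style fully convolutional network is trained per orthogonal
plane (axial, coronal, sagittal). Slices are 128 x 128 (64 x 64 in the
desk-scale preset) on a 0.75 mm isotropic grid. Each resolution block is
three repetitions of the pre-activation sequence *batch norm -> ELU ->
3 x 3 zero-padded convolution*; downsampling is 2 x 2 max pooling with
stride 2, and feature widths double per level (32 -> 512 over four levels
in the full model; 8 -> 64 over three levels in the tiny preset). The
expansive path upsamples with a stride-2 transposed convolution
(implemented as zero-insertion followed by a same-padded convolution,
equivalent up to kernel reparameterization) and concatenates the **last**
feature map of the matching contracting block. A 1 x 1 convolution and a
softmax produce per-pixel probabilities over five labels - background,
left/right inner volume of the CP, left/right CP - except in the sagittal
plane, where left and right are indistinguishable within a slice and a
3-label scheme (background / inner / CP) is used. A 3D variant (widths
8 -> 128) exists as a comparison baseline.

Weights use seeded He-uniform initialization, appropriate for the
ELU-family activations. The networks, their gradients and the optimizer
run on a small reverse-mode autodiff engine over numpy arrays
(`cpseg.nn`); all adjoints are analytic and are verified against central
finite differences in the test suite.

## Loss family

For softmax prediction p and one-hot truth g, with labels l and pixels i:

    D_l = (2 Σ_i g_li p_li + ε) / (Σ_i (g_li + p_li) + ε),   ε = 1e-5

* **Dice loss**: `1 - mean_l D_l`.
* **Focal (exponential-logarithmic) Dice loss**:
  `mean_l (-ln D_l)^γ`, γ = 0.3. With γ < 1 this steepens the gradient
  for poorly segmented labels (D below ~e^(γ-1)), countering the strong
  class imbalance of a thin CP band against background. Note the slope of
  `(-ln D)^γ` also diverges as D -> 1; the re-weighting argument applies
  to the under-segmented regime.
* **Boundary Dice loss**: the focal Dice computed on boundary residuals
  `x - (x ⊖ B)`, where ⊖ is grayscale erosion by a flat disk B of
  diameter 7 (offsets with Euclidean radius <= 3), applied per 2D slice
  and per label. Erosion borders replicate the edge pixel so constant
  maps have zero residual; for probability maps the erosion is a running
  minimum and its gradient follows the min subgradient (ties split
  equally).
* **Hybrid loss**: `L_focal(g, p) + λ · L_focal(g - g⊖B, p - p⊖B)`,
  λ = 0.1. The boundary term re-weights the few-pixel band where CP
  segmentation errors actually live, at the same value scale as the
  whole-area term. The boundary focal term reuses γ = 0.3 and includes
  all labels (a flag can exclude background).

Numerical guards: the argument of `ln` is clamped to [ε, 1]; the clamp
passes gradients through unchanged inside the interval.

## Aggregation (TTA, multi-view, MVT)

At test time each plane network predicts four flip-augmented copies of
every slice: original, horizontal, vertical, combined. Flips are undone
on the outputs before summation; a flip along the left-right in-plane
axis of an axial or coronal slice also swaps the left/right label
channels (1<->2, 3<->4). Sagittal slices carry no left-right axis: they
use the 3-label scheme, never swap, and contribute three augmented
predictions - identity, horizontal, vertical; the combined flip is
dropped. Which of the four variants to drop is not determined by the
aggregation arithmetic; the choice here preserves the total of 11
predictions (4 axial + 4 coronal + 3 sagittal) and is configurable.

Summed per-plane probability volumes are combined by voxelwise addition
followed by argmax over labels. The 3-label sagittal volume is first
broadcast to five labels by adding its inner (and CP) probability to both
the left and right channel. Probabilities are deliberately *not*
renormalized before summation, and the sagittal duplication is kept as
specified - the final argmax is unaffected by a per-plane scale but the
literal sums are what the probability outputs expose. Argmax ties break
toward the lowest label index, so exact ties go to background,
deterministically. Ablation paths (single plane, single-plane TTA,
multi-view without TTA) reuse the same machinery with restricted flip
sets.

## Preprocessing

Volumes are multiplied by the brain mask, z-scored, cropped in-plane to
the mask bounding box and zero-padded symmetrically to the square slice
size. The z-transform support is the in-mask (nonzero) voxel set: the
scans the method targets are already masked, and including the zero
background would let it dominate the statistics. The transform is applied
before padding so pad zeros sit at the post-transform background level.
Plane conventions on the RAS-ordered grid: axial stacks along
superior-inferior with in-plane (left-right, anterior-posterior) axes;
coronal along anterior-posterior with (left-right, superior-inferior);
sagittal along left-right. The horizontally drawn in-plane axis for axial
and coronal is left-right, which is what makes "horizontal flip implies
label swap" well defined. Empty slices are kept in training and
prediction. Coordinates are 0-based; crop boxes are half-open.

## Training protocol

Cases are assigned to k folds stratified on the folding-complexity
surrogate (standing in for gestational age): cases are sorted into
tertiles and dealt round-robin with a running pointer, so fold sizes and
per-fold tertile counts differ by at most one. Ten percent of each
training fold (of *cases*, not slices, to avoid intra-case leakage) is
held out for validation, spread evenly over the stratification range.
Each plane network trains with Adam, random flip augmentation (left-right
flips swap the paired labels), and early stopping: the checkpoint with
the best validation Dice (mean over foreground labels, pooled over
validation slices) is kept, and training halts after `patience_epochs`
epochs without improvement (patience 0 trains exactly one epoch).

Two presets:

| parameter | full | tiny |
|---|---|---|
| cohort | 52 cases, 128 grid | 16 cases, 64 grid |
| network | base 32, depth 4 | base 8, depth 3 |
| folds | 10 | 3 (fold 0 trained) |
| learning rate | 1e-4 | 2e-3 |
| batch / epochs / patience | 32 / <=1000 / 100 | 16 / <=8 / 8 |
| training slice stride | 1 | 3 |
| evaluated test cases | all | 2 |

The tiny preset is sized so that a complete train/evaluate cycle runs in
about two to three minutes on one CPU core: the network is two orders of
magnitude smaller than the full model and the phantom task is easier than
clinical MRI, so a larger learning rate and a short epoch budget reach a
stable segmentation; training on every third slice loses little because
neighboring phantom slices are highly redundant. The defaults above are
the package's desk-scale study conditions and are not tuned per run.

## Evaluation metrics and morphometry

* **Dice** per region on the 3D result; both-empty regions score 1, one-
  empty 0.
* **Mean surface distance (MSD)**: symmetric - boundary voxels are region
  voxels with a face-adjacent non-region neighbor; each direction's mean
  Euclidean distance (via a distance transform, in mm) to the other
  boundary is computed and the two are averaged. Empty regions raise
  rather than silently scoring 0.
* **Volume**: voxel count x voxel volume (cc).
* **Inner-CP surface**: the hemisphere's inner volume is smoothed with a
  1.5 mm FWHM Gaussian, the 0.5 isosurface is extracted by marching
  cubes in mm coordinates, the largest component kept, and the mesh
  smoothed with volume-preserving Taubin λ|μ iterations (10 iterations,
  λ = 0.5, μ = -0.53) - a dependency-free replacement for the external
  surface tool used in the original pipeline. Non-closed results raise
  with diagnostics.
* **Surface area**: per-vertex mixed Voronoi areas (circumcentric cells
  for non-obtuse triangles; obtuse triangles give half their area to the
  obtuse corner, a quarter to the others). The per-vertex areas partition
  the face area exactly.
* **Global mean curvature (GMC)**: per-vertex angular deviation - the
  angle deficit `2π - Σ incident angles` normalized by mixed vertex area
  - averaged over the surface with area weights on absolute values.
  "Angular deviation" admits more than one discrete reading; the
  angle-deficit form is used because it is coordinate-free, exactly
  satisfies discrete Gauss-Bonnet (Σ deficits = 4π on closed genus-0
  surfaces, which the tests assert), and rises with folding while
  falling with size, the behavior a folding index needs. The choice is
  isolated in one function so an alternative (e.g. mean-curvature-normal
  magnitude) can be swapped in.
* **Index agreement**: OLS slope and R² between automatic and manual
  morphometric indices over paired cases.

## What the phantoms emulate - and what they do not

Each phantom is two non-overlapping "hemispheres" on an isotropic grid: a
smooth inner ellipsoidal body wrapped by a thin (1-3 voxel) shell whose
inner and outer boundaries are radially corrugated ellipsoids
(`amplitude x sin(f·θ) sin(f·φ)`, both surfaces in phase so thickness is
preserved). A scalar complexity in [0, 1] drives fold amplitude and
frequency jointly, standing in for gestational age; intensity is the
3-level tissue mean image blurred to a partial-volume FWHM with additive
i.i.d. Gaussian noise (no Rician model - the method is intensity-model
agnostic). The left hemisphere occupies the low-x half-space; a voxel
exactly on the mid-sagittal plane counts as left (deterministic tie
rule).

This reproduces what the method's machinery depends on: a thin
corrugated target class dwarfed by background, left/right symmetry for
label-swap augmentation, partial-volume ambiguity at boundaries, and a
monotone folding covariate for stratification and morphometry. It does
*not* reproduce gyral anatomy, intensity inhomogeneity, motion or
reconstruction artifacts, inter-hemispheric asymmetry, or deep-sulcal
CSF. Passing phantom tests therefore demonstrates that the
implementation is correct and that the method's claimed orderings (MVT
over single-plane, hybrid over plain Dice at boundaries) materialize on
clean geometry - not that clinical accuracy figures transfer.

## Numerical and engineering choices

* float32 throughout; all randomness flows from one master seed (cohort,
  folds, initialization, shuffling, augmentation), so a fixed seed gives
  byte-identical result tables across runs.
* Convolutions are explicit im2col + GEMM; erosion is a running minimum
  over disk offsets with replicate borders. Both have hand-written
  adjoints checked against finite differences.
* Batch norm uses batch statistics in training and running averages in
  inference, so prediction is deterministic.
* With 128- or 64-pixel inputs every pooled size is even; the upsampling
  path asserts shape agreement instead of silently padding.
* Checkpoints (weights + config + running statistics) are npz files; the
  best-validation checkpoint is what `fit()` returns.

## Known limitations

* The 3D baseline variant is implemented and tested structurally but not
  trained in the default suite (CPU cost).
* The full-scale preset (52 cases at 128³, ten folds, patience 100) is
  faithful to the protocol but is not exercised in CI; the tiny preset
  is the tested configuration.
* Erosion border replication means residuals vanish at image borders for
  constant maps but not for structures touching the border; padded
  slices place background there by construction.
* CSF and the outer CP surface are out of scope; the morphometry stack
  covers the inner CP boundary only.
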