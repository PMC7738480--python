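# cpseg — fetal cortical plate segmentation with multi-plane aggregation

Quantifying how the fetal cortex grows and folds *in utero* requires
segmenting the **cortical plate (CP)** — the thin developing gray-matter
band — from reconstructed T2-weighted fetal MRI. The CP is a few voxels
thick, blurred by partial-volume effects, and dwarfed by background, which
defeats both atlas-based methods and networks trained with a plain Dice
loss. `cpseg` implements a segmentation pipeline built around two ideas:

1. **A hybrid loss.** With per-label smoothed Dice
   `D_l = (2 Σ_i g_li p_li + ε) / (Σ_i (g_li + p_li) + ε)`, training
   minimizes

   ```
   L_hyb(g, p) = L_focal(g, p) + λ · L_focal(g − g⊖B, p − p⊖B)
   L_focal(g, p) = mean_l (−ln D_l)^γ          γ = 0.3, λ = 0.1
   ```

   The focal (exponential-logarithmic) term steepens gradients for poorly
   segmented labels; the boundary term applies the same loss to the
   residual between each map and its grayscale erosion by a disk `B`
   (diameter 7), concentrating weight on the boundary band where thin-
   structure errors live.

2. **MVT aggregation.** One 2D U-Net (pre-activation blocks of
   BN → ELU → 3×3 conv, widths 32→512) is trained per orthogonal plane.
   At test time each network predicts flipped copies of its slices
   (with a left↔right label swap when a flip mirrors the left–right
   axis), inverse-transformed softmax maps are summed per plane, the
   3-label sagittal result is broadcast to both hemispheres, and the
   final label is the voxelwise argmax of the cross-plane sum:

   ```
   p_MVT(i) = argmax_l [ p_sum_axi(i,l) + p_sum_cor(i,l) + p_sum_sag(i,l) ]
   ```

   — 11 predictions in total (4 axial + 4 coronal + 3 sagittal).

The package also provides the evaluation stack (Dice, symmetric mean
surface distance) and surface morphometry of the inner CP boundary
(marching-cubes extraction, Taubin smoothing, mixed-Voronoi vertex areas,
angle-deficit global mean curvature), plus a **synthetic phantom
generator** — seeded two-hemisphere folded-shell volumes with tunable
folding complexity — so the entire pipeline trains, predicts and
evaluates end to end without any clinical data. Because the networks must
run where only numpy is guaranteed, the package carries its own compact
reverse-mode autodiff engine (`cpseg.nn`) with finite-difference-verified
gradients.

Who is this for: researchers reproducing or extending multi-view 2.5D
segmentation methods, and anyone needing a self-contained, dependency-light
reference implementation of the hybrid focal+boundary Dice loss, flip-TTA
with label swapping, or discrete surface morphometry.

## Worked example

```python
from cpseg import SegmentationModel, tiny_config

model = SegmentationModel.from_config(tiny_config(seed=0))  # 16 phantoms @ 64³
results = model.fit()                                       # 3 plane networks
print(results.summary(results.evaluate(
    modes=("axi", "cor", "multiview", "mvt"))))
```

Output (as printed by the run above):

```
Cortical plate segmentation - phantom evaluation
loss: hybrid  seed: 0  cases: 16 @ 64^3
         axi  CP_L  Dice 0.823 +/- 0.024  MSD 0.413 +/- 0.013 mm
         axi  CP_R  Dice 0.854 +/- 0.019  MSD 0.302 +/- 0.027 mm
         axi  in_L  Dice 0.933 +/- 0.007  MSD 0.315 +/- 0.024 mm
         axi  in_R  Dice 0.956 +/- 0.007  MSD 0.209 +/- 0.029 mm
         cor  CP_L  Dice 0.849 +/- 0.014  MSD 0.282 +/- 0.002 mm
         cor  CP_R  Dice 0.860 +/- 0.004  MSD 0.254 +/- 0.030 mm
         cor  in_L  Dice 0.966 +/- 0.004  MSD 0.188 +/- 0.031 mm
         cor  in_R  Dice 0.959 +/- 0.007  MSD 0.212 +/- 0.030 mm
   multiview  CP_L  Dice 0.893 +/- 0.012  MSD 0.213 +/- 0.003 mm
   multiview  CP_R  Dice 0.903 +/- 0.003  MSD 0.187 +/- 0.004 mm
   multiview  in_L  Dice 0.976 +/- 0.001  MSD 0.121 +/- 0.014 mm
   multiview  in_R  Dice 0.976 +/- 0.000  MSD 0.120 +/- 0.005 mm
         mvt  CP_L  Dice 0.906 +/- 0.012  MSD 0.182 +/- 0.012 mm
         mvt  CP_R  Dice 0.911 +/- 0.007  MSD 0.177 +/- 0.008 mm
         mvt  in_L  Dice 0.978 +/- 0.001  MSD 0.108 +/- 0.001 mm
         mvt  in_R  Dice 0.980 +/- 0.001  MSD 0.100 +/- 0.006 mm
```

Reading the numbers: each row is mean ± sd over the held-out phantom cases
of one fold. `in_*` are the left/right inner volumes of the CP (easy,
large regions — Dice ≈ 0.98), `CP_*` the thin cortical-plate shells (the
hard target). Aggregating more predictions helps exactly as the method
claims, in both metrics: single-plane (`axi`, `cor`) 0.82–0.86 CP Dice,
multi-view (3 predictions) 0.89–0.90, and MVT (11 predictions) best at
0.906/0.911 with the lowest boundary error (0.18 mm at 0.75 mm voxel
size) — the 3D-regularization effect that motivates multi-plane fusion.

A command-line interface mirrors the library:
`cpseg simulate`, `cpseg train`, `cpseg predict --mode mvt`,
`cpseg evaluate`, `cpseg ablate` (see `--help` for options).

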