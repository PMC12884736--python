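# surfscan

Computational pipeline for microscopy of **unsectioned, irregular tissue
surfaces** — the software side of a scanning microscope that images curved
samples (excised tumors, organs) at cellular resolution without flattening
or sectioning them, for rapid intraoperative tumor-margin assessment.

Intraoperative pathology today relies on frozen-section analysis: slow,
destructive, and limited to a handful of sectioning sites. A surface
microscope that follows the tissue's own 3D shape can instead image the
*entire* resection margin in minutes. This package implements everything
such an instrument needs between the 3D scanner and the diagnosis, and a
synthetic-fixture module that emulates the instrument so the whole pipeline
runs and is tested on a desk:

- **geometry** — surface-mesh ingestion (PLY/OBJ/STL), cleaning, the
  area-weighted surface centroid, local least-squares normals, and
  implicit-surface reconstruction from oriented point sets;
- **trajectory** — decomposition of the mesh into field-of-view-sized
  grids (centers spaced `0.8 l` for ~20% overlap), per-grid Z-X-Y Euler
  poses whose rotation matrix has the grid normal as its third column
  (tilt limit 83.3° from vertical), elevation schedules stepping the
  focus at the objective's depth of field (10–30 frames per grid), and
  rotation-minimizing path ordering;
- **calibration** — the projection model `H = A·B` with intrinsic
  `A = diag(m/du, m/du, 1)`, magnification by bundle adjustment over the
  13 chessboard dots, extrinsic fitting, the rotation-stage positional
  correction `(offset_x, offset_y, 1)ᵀ = Ĥ⁻¹·(O_x − N/2, O_y − N/2, 1)ᵀ`,
  circle fitting for the R_z axis, and linear-stage skew fitting;
- **fusion** — FOV arithmetic `l = du · pixel_N / m` and extended
  depth of field by Laplacian-pyramid fusion of per-grid focal stacks;
- **synthesis** — homography projection of fused tiles onto mesh facets,
  Markov-random-field view selection, Poisson (gradient-domain) seam
  blending, intensity inversion, a Beer–Lambert pseudo-H&E colormap, and
  the colour-moment loss
  `L_color = MSE(Mean_a, Mean_b) + MSE(Std_a, Std_b)`;
- **cad** — 128×128 subimage tiling (≈0.12 mm at 5×), K-means nucleus
  segmentation, the four margin features (nucleocytoplasmic ratio,
  average nuclear intensity, mean and SD of nuclear cross-section area),
  section-distance filtering (0.5 mm band), artifact exclusion, 6:4
  stratified splitting, logistic-regression margin model (IRLS), and ROC
  evaluation with Wilson confidence intervals;
- **synthetic** — generators for surfaces, fluorescence tissue textures
  with ground-truth nucleus masks, focal stacks, calibration scenes, and
  labelled margin datasets.

## Worked example

```bash
python examples/03_fuse_focal_stack.py
```

```
sharpness (Tenengrad, relative to the all-sharp reference):
  frame at -0.20 mm: 0.057
  ...
  frame at +0.05 mm: 1.000
  frame at +0.10 mm: 0.584
  ...
  fused tile        : 0.998
```

Nine frames of one grid, blurred in proportion to their distance from the
focus plane at +0.05 mm, are fused into a single tile that retains 99.8%
of the sharp reference's Tenengrad sharpness — no single frame of a real
stack is sharp everywhere on a curved surface, which is why the fusion
step exists.

```bash
python examples/05_classify_margins.py
```

```
test AUC 1.000; per-feature AUCs: {'nc_ratio': 1.0, ...}
sensitivity 100.0% (95% CI 91.2%-100.0%), specificity 100.0% (95% CI 91.2%-100.0%)
```

200 labelled synthetic subimages (positive-margin tissue has denser,
larger, brighter nuclei) are split 6:4; the combined four-feature logistic
model separates the held-out set completely. On synthetic data the classes
are well separated by construction; the run demonstrates the machinery,
not clinical performance.

The other examples cover trajectory planning (`01`), calibration (`02`),
pseudo-H&E rendering (`04`), and the full pipeline (`06`), which writes
seven artifacts (mesh, trajectory JSON, fused tiles TIFF, textured OBJ,
feature CSV, model JSON, evaluation JSON) into a run directory. A thin
CLI wraps the same functions: `surfscan simulate | plan | calibrate |
fuse | synthesize | render | features | train | evaluate | run`.

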