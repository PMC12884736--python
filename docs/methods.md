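# Methods

This note documents the models, numerical choices, and deliberate
conventions behind each stage of the pipeline, and what the synthetic
fixtures do and do not establish about real instrument data.

## Coordinate and unit conventions

Geometry lives in millimetres in a right-handed instrument frame: origin
at the calibration-chessboard centre, z up. Image pixels are 0-based,
row-major, origin top-left, with x mapping to columns. Inside the
projection model units are micrometres (the sensor pitch `du` is given in
µm); conversions are explicit at module boundaries. The field-of-view
centre is taken at `(pixel_N/2, pixel_N/2)` exactly, with no half-pixel
shift, for fidelity to the positional-correction formula as written.

## Surface geometry

**Cleaning.** Isolated vertices are those with no neighbour within
`isolation_radius` (default 2 mm — about four times the fixture-mesh
spacing; the rule only needs to separate stray scanner returns from the
connected surface). Smoothing is uniform-weight Laplacian with step
λ = 0.5: each vertex moves halfway to the mean of its edge-connected
neighbours per iteration. The operation is idempotent at fixed
parameters once the vertex set is stable.

**Surface centroid.** The scan seed is the area-weighted average of facet
centroids. For curved meshes this point lies off the surface; it is then
snapped to the nearest mesh *vertex* rather than the nearest facet point.
Projection onto facets is ill-conditioned exactly where it matters most —
an axis-symmetric interior point is equidistant from the whole apex facet
fan of a dome, and the winner of that tie lands arbitrarily off-axis —
while vertex snapping preserves symmetry axes of symmetric tessellations.
An on-surface centroid (flat meshes) is kept exactly.

**Local normals.** The k-nearest-vertex neighbourhood (default k = 12)
is fit by total least squares (smallest principal component); the normal
is oriented by the neighbourhood's mean stored vertex normal. A
neighbourhood whose second singular value vanishes (collinear points) is
rejected.

**Reconstruction from oriented points.** No installed library provides a
screened-Poisson reconstruction, so the package fits a smooth implicit
signed field by radial-basis interpolation of on-surface (value 0) and
offset (±ε along the normal, ε = 5% of the point-cloud extent)
constraints, evaluates it on a 64³ grid padded by 15% of the extent, and
extracts the zero level set with marching cubes. Planar inputs (third
singular value ≈ 0) fall back to 2D Delaunay triangulation in the plane.
Measured accuracy on a 500-point sphere of radius 7.5 mm: mean
point-to-surface distance ≈ 0.002 mm, well inside the 0.1 mm contract;
the error budget is dominated by marching-cubes linearisation,
O(h²·curvature) with h ≈ 0.3 mm.

## Trajectory planning

**Grid propagation.** Planning starts at the surface centroid and grows
breadth-first. At each grid centre the four step directions are the ±x
and ±y axes projected onto the local tangent plane (when the normal is
parallel to a reference axis, a deterministic orthonormal tangent pair
derived from the normal's smallest component substitutes). Candidate
neighbour centres sit at `overlap_factor · l` along each direction
(default 0.8, giving ~20% FOV overlap for image registration); off-surface
candidates snap to the nearest surface point, candidates within
`0.5 · overlap_factor · l` of an existing centre merge with it, and a
candidate whose footprint adds no new member vertices is discarded — that
is the mesh-boundary termination. Grid membership is the `l × l` square
footprint in the grid's own tangent frame. A final repair pass seeds an
extra grid at any vertex left unassigned, so vertex coverage is total by
construction. Planning is deterministic and bit-reproducible: there is no
randomness anywhere in the planner.

On flat meshes this produces an exact `0.8 l` centre lattice (verified to
1e-9). The guaranteed chordal bound from centre to covered vertex is
`l/√2`; on a hemisphere of radius 7.5 mm the measured maximum is
≈ 0.66 l (curvature and snapping distort the lattice, and a plain 0.8 l
lattice already has a flat-case worst distance of 0.566 l, so no tighter
bound should be expected of this propagation rule).

**Poses.** The Z-X-Y Euler convention composes `R = Rz(rz)·Rx(rx)·Ry(ry)`;
the optical axis is the third column. Given a grid normal `n`, with
rz = 0, the closed form is `rx = atan2(−n_y, n_z)`,
`ry = atan2(n_x, hypot(n_y, n_z))`. Tilt beyond 83.3° from vertical — the
rotation stages' mechanical limit — raises. The linear stages place the
lens at `centre + working_distance · n`.

**Elevation schedules.** The focus sweep spans from 0.2 mm below the
lowest member vertex to 0.2 mm above the highest (projected on the grid
normal); the pad absorbs 3D-scanner error. The step never exceeds the
objective's depth of field, and the frame count is clamped to [10, 30]
with even re-spacing when the clamp binds (spacing = padded span / (n−1)).
Objective presets (5×: DOF 0.05 mm, WD 34 mm; 10×: 0.025/34; 20×:
0.012/20) are configuration values typical of long-working-distance
plan-apochromats; only magnification, `du` = 4.5 µm, and
`pixel_N` = 5120 enter the FOV arithmetic.

**Path ordering.** Visiting order minimises rotation-stage motion
greedily: nearest neighbour from the centroid grid under cost
`|Δrx| + |Δry| + 0.01 deg/mm · ‖Δxyz‖` (the linear term is a
tie-breaker). Greedy nearest-neighbour alone cannot guarantee beating an
arbitrary given order, so the planner returns whichever of {greedy tour,
input order} is cheaper; on ≤ 8 grids the result is benchmarked against
the exhaustive optimum in tests. rz does not participate in the cost: the
sample-rotation stage is set per quadrant, not per grid, by `confine_quadrant`,
which picks the multiple of 90° mapping the target into x ≥ 0, y ≥ 0
(smallest rotation first; axis points count as quadrant I).

## Calibration

The microscope is an infinity-corrected system: intrinsics
`A = diag(m/du, m/du, 1)` in px/µm, extrinsics carrying two rotation rows
and a translation, homography `H = A·B` mapping board-plane µm to pixel
displacements from the FOV centre.

**Magnification** ("bundle adjustment" over the 13 dots) is a joint fit
of (scale, in-plane rotation, translation): the closed-form Procrustes
similarity solution initialises a Gauss–Newton refinement (finite-
difference Jacobian, convergence on step norm < 1e-14). `m = scale · du`.
Noise-free recovery is exact to machine precision; at 0.1 px noise the
error is below 0.01. When the true pose is tilted, the similarity model
absorbs cos(tilt) into the scale, so chained estimates (m, then B given m)
carry a small consistent bias — the instrument's own procedure iterates
orientation and re-measurement for the same reason.

**Extrinsics** solve the linear least-squares problem for
(r11, r12, tx, r21, r22, ty); r13 and r23 complete each rotation row to
unit norm (non-negative root — the sign is unobservable from a single
planar view). The parallelism metric is the distance of the 2×2 block
from an orthonormal pair plus |r13| + |r23|; the implied tilt is
arccos of the block's smaller singular value.

**Rotation-stage corrections** apply the printed inverse-homography
formula verbatim, renormalising the homogeneous component. Corrections
between calibrated step angles are piecewise-linear; extrapolation
outside the calibrated range is refused rather than guessed. The R_z axis
comes from a Kåsa (algebraic) circle fit — closed-form and deterministic;
at the µm noise scale of the fixtures its known bias relative to the
geometric fit is negligible (centre error < 2 µm at 1 µm noise).
Linear-stage skew is the signed angle between a total-least-squares line
and the named axis.

## Focal-stack fusion

Each frame is decomposed into a Laplacian pyramid (5-tap binomial kernel
[1,4,6,4,1]/16, reflect borders, depth 5 or until a level falls under
8 px). At every level and coefficient the frame with the largest absolute
coefficient *aggregated over a 3×3 neighbourhood* is selected, ties
breaking toward the lower frame index; the coarsest Gaussian level is
averaged. The neighbourhood aggregation matters: raw per-coefficient
argmax mis-selects ~30% of coarse-level coefficients on periodic textures
(the pattern aliases toward Nyquist after repeated downsampling, and an
aliased blurred coefficient can exceed the sharp one), costing ~5% of
reference sharpness; aggregation restores ≥ 98%. The reconstruction is
clipped to the stack's intensity range, and the level-0 argmax is kept as
a per-pixel provenance map.

Histogram equalization (256 bins, cumulative mapping anchored so the
lowest occupied bin maps to 0) runs per tile *after* fusion and spreads
the tile to the full range of its dtype; constant tiles pass through
unchanged, and re-equalization moves pixels by at most one quantization
step.

## Surface synthesis

Tiles are projected through the pose-composed homography: a surface point
is expressed in the camera frame (axes = pose rotation columns, origin at
the pose target), its in-plane mm coordinates become µm, pass through Ĥ,
and are offset to the tile's pixel centre. Facets whose centroid lands
inside the tile footprint receive per-vertex texture coordinates; the
forward/backward composition round-trips exactly on the tile plane.

View selection is a pairwise Markov random field: unary cost
`1 − cos(angle between facet normal and tile viewing axis)`, pairwise
cost λ (default 0.5) per edge-adjacent facet pair with differing labels.
It is solved by iterated conditional modes from the best-unary
initialisation with ordered sweeps — deterministic, energy
non-increasing, exact at λ = 0, and within 5% of the exhaustive optimum
on the small fixtures where enumeration is feasible. ICM was chosen over
graph cuts for determinism and zero dependencies; the energies involved
are tiny (tile viewing angles differ little after planning).

Brightness seams are removed by gradient-domain editing: per patch, the
discrete Poisson equation with the source patch's own Laplacian as
interior target, natural (mirrored Neumann) boundaries, and Dirichlet
values at seam pixels fixed to the across-seam average. A constant
brightness offset between patches is removed entirely (each patch's
harmonic solution is the shifted constant); identical patches pass
through unchanged; interior Laplacians are preserved to solver tolerance
(sparse direct solve, residual checked against 1e-6).

**Rendering.** Intensity inversion is `I_max − I` (dtype maximum for
integer images), making fluorescence-bright nuclei dark as in H&E. The
pseudo-H&E colormap is Beer–Lambert absorption,
`RGB = 255·exp(−(c_H·nuclear + c_E·background))`, with the standard
hematoxylin (0.65, 0.70, 0.29) and eosin (0.07, 0.99, 0.11) RGB
absorption vectors: zero signal renders white, nuclear signal darkens
toward blue-purple (B ≥ R > G), and the map is monotone per channel.
This is a deterministic stand-in for learned stain transfer, which is out
of scope; of that machinery only the colour-moment loss is implemented —
`MSE(mean_a, mean_b) + MSE(std_a, std_b)` over per-channel moments,
averaged over channels by default (a `reduction="sum"` switch preserves
the summed variant, since either reading of "MSE between vectors" is
defensible). The loss is symmetric and invariant to spatial permutations
by construction.

## Margin classification

Tiles are cut into non-overlapping 128×128 subimages from the top-left;
partial edge tiles are discarded, never padded (padding would dilute
features with synthetic pixels). At 5× the footprint is
128 · 0.9 µm = 115.2 µm ≈ 0.12 mm. Only subimages within 0.5 mm of the
histology sectioning line are analysed, so labels transfer from the
stained sections; distance is Euclidean in the surface's tangent-plane
coordinates. Artifact regions (scratches, hemorrhagic necrosis — both
mimic tumor fluorescence) are supplied as an annotation mask; subimages
overlapping it by more than 10% of their area are excluded.

Nuclei are segmented by 2-cluster K-means on raw pixel intensity (fixed
seed, 10 restarts, k-means++ initialisation); the brighter cluster is
nuclei — the fluorescence convention, applied before any display
inversion. Connected components use 8-connectivity. A constant patch
yields an empty mask, and its feature vector is zeroed and flagged
excluded rather than fabricated. The four features are the nucleus pixel
fraction (NC ratio), mean patch intensity over the mask, and the mean and
SD of component areas in pixels (SD = 0 for a single nucleus).

The split is seeded and label-stratified, `round(0.6·n)` per class to
training. The logistic model standardises features with training
mean/SD and fits by iteratively reweighted least squares with an L2 ridge
of 1e-6 on the slopes only (a numerical guard that also bounds the
separable case), converging when the log-likelihood moves < 1e-8; the
inverse penalised Fisher information provides Wald intervals. The fit is
cross-checked against scikit-learn's solver in the test suite but not
delegated to it, because the covariance and standardisation bookkeeping
are part of the model object. The operating threshold is the
Youden-optimal point (max TPR − FPR) of the *training* ROC — a documented
choice; no threshold rule is canonical. Evaluation reports the ROC,
trapezoid AUC (equal to the Mann–Whitney win probability, verified
against brute-force pairwise comparison), sensitivity and specificity at
the stored threshold with Wilson 95% intervals, and per-single-feature
AUCs (orientation-free, `max(AUC, 1−AUC)`). Positive-margin areas are
8-connected components of positive subimage calls times the subimage
footprint; a single positive call at 5× is 0.1152² ≈ 0.0133 mm².

## Synthetic fixtures

The generators are pure functions of (parameters, seed) — repeated calls
are bit-identical.

*Surfaces* cover the instrument's working envelope (~15 × 15 mm, height
variation up to ~10 mm): plane, hemisphere/half-ellipsoid domes with
analytic normals, and a "bumpy" plane whose height field is
Gaussian-filtered seeded noise scaled to a stated amplitude.

*Tissue textures* place nuclei by Poisson-disk dart throwing at a stated
density, minimum spacing one mean radius (relaxed to 0.3 radii for the
"disorganised" positive class), radii Normal(mean, sd) truncated
positive, rendered as bright disks (defaults 12000 vs 4000 cytoplasm in
the 16-bit range, matched to a visible but noisy fluorescence contrast)
over Gaussian read noise (σ = 300). The paired class defaults —
positive: 2200 nuclei/mm², radius 5.5 µm, brighter and disorganised;
negative: 800 nuclei/mm², radius 4.0 µm — encode the qualitative
malignancy contrast (higher NC ratio, larger crowded nuclei, stronger
staining) with clearly separated feature distributions.

*Defocus* is an isotropic Gaussian blur with σ = blur_scale ·
|elevation − focus|; the real optical PSF is out of scope. *Calibration
scenes* project the 13-dot chessboard model (4 mm squares, centre dot at
the origin, 12 symmetric auxiliary dots) through a known `H = A·B` with
seeded pixel noise.

**What passing tests show — and don't.** The fixtures exercise geometry,
numerics and statistical machinery end to end, and the classifier's
perfect synthetic AUC demonstrates the pipeline, not clinical accuracy:
real tissue has heterogeneous textures, out-of-focus haze, staining
variability, and class overlap that the generators deliberately do not
model. Published headline accuracies on animal or human tissue cannot be
reproduced from synthetic data and are not claimed.

## Problem sizes

Defaults are desk-scale: fixture meshes of a few hundred to a few
thousand vertices, simulated tiles of 256–384 px standing in for the
5120 px sensor (the physical FOV is unchanged; only the simulated pixel
pitch coarsens), classifier datasets of a few hundred subimages, and
inference checks at n = 5000. The full demo pipeline runs in a few
seconds on one CPU; the acceptance script in a few minutes.

## Known limitations

- The planner's propagation can over-seed on strongly curved meshes
  (merge radius 0.4 l is a convention); coverage is guaranteed, minimal
  grid count is not.
- ICM view selection is a local optimiser; the 5% optimality margin is
  verified only on small fixtures.
- The Poisson seam solver operates per patch with seam-averaged Dirichlet
  values, which removes brightness steps but does not jointly optimise
  all patches.
- The chained calibration (m, then B given m) inherits the similarity
  fit's cos(tilt) bias at large initial tilts, as noted above.
- `estimate_extrinsic`'s r13/r23 sign is fixed non-negative; a single
  planar view cannot observe it.
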