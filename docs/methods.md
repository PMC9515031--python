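# Methods

This note documents the models, conventions, numerical choices and known
limitations of the package, in the order the pipeline applies them.

## Coordinate conventions

All world quantities are millimetres in LPS (left, posterior, superior).
Volumes carry per-axis spacing, the world position of the centre of voxel
(0,0,0), and an orientation matrix; the world coordinate of index i is
`origin + orientation @ (i * spacing)` (voxel-centre convention). Analysis
routines require *canonical* volumes (grid axes aligned with +L, +P, +S);
`read_volume` canonicalizes axis-aligned acquisitions on load and rejects
oblique ones with a request to resample first. In-memory index↔world round
trips are exact to < 1e-9 mm. NIfTI-1 stores affines in float32, so
geometry read from disk agrees with what was written to ~1e-7 relative
(data values round-trip exactly; a write–read–write cycle is
byte-identical). DICOM series reading (via ITK, which is LPS-native) is a
convenience path; NIfTI is the reference format.

Grid utilities follow the preprocessing used for localization on clinical
hip MRI: standardization to 768 × 672 × 160 voxels (symmetric pad with a
background value, or centre-crop; retained voxels keep their world
coordinates), in-plane 2× block-average downsampling of the axial path to
384 × 336, and a 368 × 368 × 96 crop whose central voxel is the voxel
nearest the femoral-head centre (near a boundary the crop pads rather than
shifts, keeping the centre central). Padding defaults to 0 for label
volumes and the volume minimum for images.

## Shell phantoms

Synthetic ground truth is a patch of a spherical shell: voxels with
`r_inner ≤ |p − centre| ≤ r_outer` whose polar angle from a symmetry axis
and azimuth from a reference axis lie in stated half-open bands
(`[min, max)`; the degenerate band `min = max` is empty, and the full
azimuth (0, 360) covers everything, so boundary voxels are never counted
twice). Closed forms for the patch: solid-angle fraction
f = Δaz/360 · (cos φ_min − cos φ_max)/2, volume f·(4/3)π(r_o³ − r_i³),
mid-surface area f·4πr_mid², thickness r_o − r_i. Defaults mirror the
clinical scale — a ~44 mm mid-surface radius with a 3 mm shell, since
weight-bearing hip cartilage is only 3–4 mm thick — at 0.5 or 1 mm
isotropic spacing for fast tests. Optional surface jitter perturbs the
inner/outer radii per 2° angular bin with seeded Gaussian noise,
emulating segmentation surface error.

What the phantom does **not** emulate: MRI texture and noise, bone and
labrum structures, the true (non-spherical-band) lunate outline, partial
volume at the cartilage surface, and spatially correlated segmentation
errors. Passing tests therefore demonstrate the correctness of the
geometric and metric machinery, not segmentation performance on patients.

## Femoral-head localization

The target representation is a Gaussian of the *world* distance to the
centre, `exp(−|p−c|²/2σ²)`, σ default 10 mm: iso-surfaces are spheres in
mm regardless of voxel anisotropy, and the argmax sits at the centre. Two
per-plane 2D predictors (axial, coronal) emit per-slice heatmaps; each
plane's predictions are stacked into a 3D volume. A 2D prediction is
uninformative along its own stacking axis, so the two stacks are fused by
voxelwise multiplication, which cancels the ambiguity and reconstructs a
peaked 3D heatmap; the argmax voxel's world coordinate is the predicted
centre. Ties are broken at the lowest lexicographic index and reported
with a warning. The downsampled axial stack is linearly resampled onto
the standardized grid before multiplication. Predictors are a pluggable
seam (registry keyed by name): the shipped reference predictors are an
exact-Gaussian oracle (for verification) and an intensity-weighted
centroid predictor that works on bright-ball images; trained 2D networks
can be plugged in without code changes. With exact Gaussian slice
predictions the recovered centre is within half a voxel per axis of the
truth for any centre and anisotropic spacing — the attainable bound for an
argmax on a grid.

## Ensemble fusion and post-processing

Per-plane binary segmentations are combined by voxelwise majority vote
(≥ 2 of 3), then the largest connected component is kept. Vote precedes
component extraction. Default connectivity is 26; thin oblique shells
fragment under 6-connectivity. Size ties keep the smallest label of the
deterministic labelling order, with a warning.

## Sphere fit and anatomical frame

The algebraic least-squares sphere fit solves the linearized system
`[2p, 1]·[c; r²−|c|²] = |p|²` on mean-centred points; rank deficiency
detects coplanar/collinear degeneracy. An optional single Gauss–Newton
pass refines the geometric residuals (off by default; on exact data the
algebraic fit is already exact to 1e-6 mm, and on symmetric shells it
lands on the mid-surface within 0.1 mm centre / 0.2 mm radius at 0.5 mm
spacing). On partial lunate patches the algebraic fit carries a small
intrinsic bias (~0.1–0.2 mm centre at 0.5 mm spacing, < 1 mm in all tested
configurations).

"First mechanical principal axis" is interpreted as the inertia-maximal
(covariance-minimal) direction — the symmetry axis of a lunate band, and
the only reading under which a clock face "perpendicular" to it is
sensible. An ambiguity error (listing the eigenvalue gaps) is raised when
the two smallest covariance eigenvalues differ by less than 1% of the
largest, as for a full shell. The frame is then Z =
normalize((centroid − c) − ((centroid − c)·Y)Y), X = Y × Z; if X opposes
the anterior direction (default −P in LPS, overridable), Y is negated and
X recomputed, so 3 o'clock is anterior for both left and right hips. The
12 o'clock anchor is the centroid-derived Z; an optional user-supplied
6-o'clock landmark (e.g. the acetabular teardrop) re-anchors the clock via
`clock_offset_from_landmark`. Automatic teardrop detection is out of
scope.

## Sectioning

Sectors are equal half-open wedges `[a, b)` of the clock angle
θ = atan2(d·X, d·Z) starting at 12 o'clock; boundary ties go to the
higher-index sector. This makes sector counts nest exactly between n and
2n sectors and partition the cartilage exactly for any n. Layers split at
the fitted mid-layer sphere (ρ < r femoral, ρ ≥ r acetabular — the tie
goes to acetabular); distances to actual bone surfaces are not used since
bone is not segmented, following the midline-separation approach. The
central/peripheral cone's half-angle defaults to `auto` = the cartilage's
median polar angle from Y's cartilage-facing pole (Y oriented so the
cartilage lies on its positive side), splitting the volume ≈ 50/50; the
angle used is logged in the provenance block.

## Quality metrics

* dGEMRIC index: arithmetic mean T1 over the section's voxels. Empty
  sections report NaN (missing), never zero, to keep cohort averaging
  honest.
* Volume: voxel count × voxel volume, exact by construction.
* Surface area: the fitted sphere is represented by N near-equidistant
  unit vectors from the offset Fibonacci lattice (deterministic; the
  degenerate N = 1 case returns the pole). Each point samples the mask
  radially over `r ± 2 mm` at half-the-smallest-spacing steps
  (nearest-neighbour lookup); a point that hits cartilage is assigned to
  the section of the hit nearest the fitted radius, and
  S = N_section/N · 4πr². One fitted r is used for all sections,
  including layer-specific ones. Doubling N changes section areas by
  < 0.5% on default phantoms; against analytic patch areas the estimator
  is within ~1–3% (edge bias from voxelized patch boundaries is positive
  and shrinks with spacing).
* Thickness: volume / surface area per section.
* Evaluation: Dice 2|A∩B|/(|A|+|B|) (1.0 when both empty, by convention);
  Hausdorff is the true maximum (no percentile) of directed
  boundary-to-boundary distances on voxel-centre world coordinates
  (6-connectivity boundary extraction); the average surface distance is
  the mean of the two directed means.

## Projection maps

Cartilage voxels project to (azimuth, inclination) bins of the frame
(default 360 × 180, 1° bins). Thickness: the local thickness of a voxel is
twice its corrected Euclidean distance to the nearest background voxel —
the EDT measures centre-to-centre, overestimating the distance to the
physical interface by about half a voxel, so half the smallest spacing is
subtracted per side before doubling; per bin the maximum is kept
(non-maximum suppression). On a 3 mm shell this recovers 3.0 mm within
half a voxel at both 1 mm and 0.5 mm spacing; estimates remain
voxelization-limited to about one voxel. dGEMRIC maps are per-bin means
over the requested layer's voxels (femoral, acetabular, or both). Bins
with no projecting voxel are NaN. Solid-angle bin weights are provided for
area-weighted averaging, which reproduces the volumetric index within 2%
on smooth fields. Rendering onto 3D surfaces is out of scope; maps export
as arrays/PNG with a min/max/units sidecar.

## Pipeline, determinism and problem sizes

`analyze` wires the stages with staged errors naming the failing stage and
writes CSV/JSON reports (sorted keys, no timestamps — two runs on the same
inputs are byte-identical), label volumes and maps. The provenance block
(sphere, frame, sector count, cone angle, N, search range, version)
suffices to re-run the identical analysis. The only randomness anywhere is
phantom jitter, which is seed-controlled.

Default verification sizes: phantoms at the clinical scale (r_mid 44 mm)
use 0.5–1 mm isotropic grids (≈ 100³–200³ voxels); the parameter-recovery
sweep uses 20 phantoms with r_mid 15–35 mm, thicknesses 2–4 mm and varying
angular extents at 0.5 mm spacing; surface areas use N = 100 000 points
with the ±2 mm search. A full phantom analysis takes seconds on one CPU.

## Known limitations

* The layer split is geometric (mid-sphere), not anatomical; without leg
  traction the true femoral/acetabular interface is not resolvable in MRI.
* Surface areas assume the cartilage is well approximated by a sphere at
  radius r; strongly aspherical heads (severe cam deformity) violate this.
* No trained segmentation or localization networks are shipped; the
  predictor seam and the fusion/post-processing operate on any external
  predictions.
* T1-map reconstruction, B1 correction and registration between the
  morphological and T1 volumes are out of scope; the two inputs are
  assumed aligned.
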