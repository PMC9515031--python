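# hipcart

Automated 3D parametrization of hip cartilage from MRI: clock-face
sectioning in an anatomically defined coordinate frame and per-section
quality metrics (dGEMRIC index, volume, surface area, thickness), plus a
femoral-head localization framework, segmentation post-processing and
evaluation metrics, 2D projection maps, and an analytic shell-phantom
generator for verification.

## Who this is for

Assessing hip cartilage degeneration — for instance when planning
joint-preserving surgery in femoroacetabular impingement or hip dysplasia —
requires both morphological measures (thickness, volume, load-bearing
surface area) and biochemical ones (the dGEMRIC index: mean post-contrast
T1 relaxation time, which falls as glycosaminoglycan is depleted). Because
degeneration is regionally heterogeneous, these measures are needed per
region: per clock-face sector of the acetabulum, separately for the femoral
and acetabular cartilage layers, and for central vs peripheral zones. This
package provides that regional parametrization for any segmented cartilage
mask, independent of how the segmentation was produced.

## The model

Given a binary cartilage mask and an aligned T1_GD map (both in LPS world
coordinates, mm):

1. **Sphere fit.** The femoral head is recovered by an algebraic
   least-squares sphere fit to the cartilage voxels: expanding
   |p − c|² = r² linearizes to 2p·c + (r² − |c|²) = |p|², solved in closed
   form. The shell straddles the head surface, so the fit lands on the
   cartilage mid-layer.
2. **Anatomical frame.** Y is the cartilage's first mechanical principal
   axis (covariance-minimal direction — the symmetry axis of the lunate
   patch); Z points from the sphere centre toward the cartilage centroid
   projected perpendicular to Y (12 o'clock); X = Y × Z, with Y's sign
   chosen so X points anterior — 3 o'clock is anterior in both hips.
3. **Sectioning.** Each cartilage voxel gets a clock angle
   θ = atan2(d·X, d·Z), a layer (femoral if |p − c| < r, else acetabular)
   and a region (central if the polar angle from Y's cartilage-facing pole
   is below a cone half-angle; `auto` uses the median polar angle).
4. **Metrics.** Per section: dGEMRIC index = mean T1 (ms); volume =
   voxel count × voxel volume; surface area from N near-equidistant sphere
   points (Fibonacci lattice, N = 100 000) that each search ±2 mm radially
   for cartilage,

   S_section = N_section / N · 4πr²,

   and thickness = volume / surface area.
5. **Maps and evaluation.** 2D (azimuth, inclination) maps of local
   thickness (per-bin maximum) and of radially averaged dGEMRIC per layer;
   Dice, Hausdorff and average surface distance for comparing masks.

Femoral-head localization is also included as a pluggable framework: 2D
per-slice heatmap predictors on the axial and coronal planes are stacked
and fused by voxelwise multiplication, and the argmax of the fused 3D
heatmap is the predicted centre. Trained plane networks can be plugged in;
the package ships an exact-Gaussian oracle and a non-learned
intensity-centroid predictor.

## Worked example

```
python examples/01_phantom_section_report.py
```

builds a 3 mm-thick lunate shell phantom on a 44 mm head, fits the sphere
and prints the four-sector report:

```
fitted sphere: centre [-0.   -0.22  0.13] mm, radius 43.85 mm (truth mid-surface 44.00 mm)
            row sector clock layer region  voxel_count  volume_mm3  surface_mm2  thickness_mm  dgemric_ms
        overall    all   all   all    all        20830     20830.0  7045.690765      2.956417       500.0
sector_marginal      1  12-3   all    all         5386      5386.0  1812.957370      2.970837       500.0
sector_marginal      2   3-6   all    all         5029      5029.0  1708.558865      2.943416       500.0
sector_marginal      3   6-9   all    all         5029      5029.0  1709.283855      2.942168       500.0
sector_marginal      4  9-12   all    all         5386      5386.0  1814.890676      2.967672       500.0
```

The fitted radius sits at the shell mid-surface, the overall thickness
(volume/area) recovers the true 3 mm within 1.5%, and the painted 500 ms
T1 field is reproduced exactly in every sector. The other examples cover
localization (`02`), ensemble fusion + evaluation (`03`) and projection
maps (`04`). The same pipeline is available from the shell:

```
hipcart analyze --t1 t1.nii --mask cartilage.nii --out results/ --sections 4
hipcart evaluate auto_mask.nii manual_mask.nii
```

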