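"""Project cartilage thickness and dGEMRIC onto 2D surface maps.

Voxels are mapped to (azimuth, inclination) bins of the anatomical frame;
thickness bins keep the local maximum (non-maximum suppression), dGEMRIC
bins the radial average per cartilage layer.
"""

import numpy as np

from hipcart import dgemric_map, frame_from_mask, make_shell_phantom, thickness_map
from hipcart.phantom import PhantomTruth

truth = PhantomTruth(polar_range=(20.0, 110.0), azimuth_range=(-80.0, 80.0))
t1_map, mask, truth = make_shell_phantom(truth, spacing=(1.0, 1.0, 1.0), t1=520.0)
sphere, frame = frame_from_mask(mask)

tmap = thickness_map(mask, sphere, frame, bins=(72, 36))
covered = tmap.values[np.isfinite(tmap.values)]
print(f"thickness map: {covered.size} of {tmap.values.size} bins covered, "
      f"median {np.median(covered):.2f} mm, max {covered.max():.2f} mm "
      f"(true shell thickness {truth.analytic_thickness:.1f} mm)")

for layer in ("femoral", "acetabular", "both"):
    dm = dgemric_map(t1_map, mask, sphere, frame, bins=(72, 36), layer=layer)
    vals = dm.values[np.isfinite(dm.values)]
    print(f"dGEMRIC map [{layer:>10}]: mean {vals.mean():.1f} ms over "
          f"{vals.size} bins")

print("\nOn this uniform phantom every covered bin sits at the painted T1;"
      "\nbins interior to the patch reach the true thickness while bins at"
      "\nthe patch rim see only a partial shell. On patient data these maps"
      "\nreveal focal thinning and glycosaminoglycan loss.")
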