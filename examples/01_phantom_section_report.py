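"""Section a synthetic cartilage shell and print its quality metrics.

Builds a lunate-shaped shell phantom (inner radius 42.5 mm, outer 45.5 mm,
i.e. 3 mm thick on a ~44 mm femoral head) with a constant 500 ms T1 field,
fits the femoral-head sphere, constructs the anatomical clock-face frame
and reports per-section dGEMRIC index, volume, surface area and thickness.
"""

import numpy as np

from hipcart import (
    build_section_report,
    frame_from_mask,
    make_shell_phantom,
    section_label,
)
from hipcart.phantom import PhantomTruth

truth = PhantomTruth(polar_range=(20.0, 110.0), azimuth_range=(-80.0, 80.0))
t1_map, mask, truth = make_shell_phantom(truth, spacing=(1.0, 1.0, 1.0), t1=500.0)

sphere, frame = frame_from_mask(mask)
print(f"fitted sphere: centre {np.round(sphere.centre, 2)} mm, "
      f"radius {sphere.radius:.2f} mm (truth mid-surface {truth.r_mid:.2f} mm)")

labeling = section_label(mask, frame, sphere, n_sectors=4)
report = build_section_report(t1_map, mask, labeling, sphere, n_points=100_000)

print(report[report.row.isin(["overall", "sector_marginal"])].to_string(index=False))
print(
    "\nEach row gives the mean T1 (dGEMRIC index, ms), the voxel-count volume"
    "\n(mm^3), the point-sampled surface area (mm^2) and thickness = volume /"
    "\narea (mm). The overall thickness should sit near the phantom's true"
    f"\n{truth.analytic_thickness:.1f} mm shell thickness."
)
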