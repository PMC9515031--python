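"""Fusion and clean-up of per-plane segmentation predictions.

The original system segments the cartilage with three plane networks
(axial, coronal, sagittal); their binary predictions are combined by a
voxelwise majority vote and the largest connected object is kept as the
segmentation result. Both steps are implemented here on arbitrary binary
label volumes so any external segmenter can feed them.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .volumes import LabelVolume, require_same_geometry

__all__ = ["majority_vote", "largest_component"]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _check_binary(mask: LabelVolume) -> None:
    if mask.data.size and mask.data.max() > 1:
        raise ParameterError("expected a binary mask (labels 0/1)")


def majority_vote(masks) -> LabelVolume:
    """Voxelwise majority over three binary masks: 1 iff >= 2 of 3 are 1."""
    masks = list(masks)
    if len(masks) != 3:
        raise ParameterError(f"majority vote expects 3 masks, got {len(masks)}")
    for m in masks:
        _check_binary(m)
    require_same_geometry(*masks)
    votes = sum((m.data > 0).astype(np.int32) for m in masks)
    return masks[0].replace(data=(votes >= 2).astype(np.uint8))


def largest_component(mask: LabelVolume, connectivity: int = 26) -> LabelVolume:
    """Keep only the largest connected foreground component.

    ``connectivity`` is 6, 18 or 26 (face / face+edge / full neighbourhood);
    26 by default since thin oblique shells fragment under 6-connectivity.
    Ties are broken by the smallest component label of scipy's deterministic
    labelling order, with a warning; an empty mask passes through with a
    warning.
    """
    _check_binary(mask)
    if connectivity not in _STRUCTURES:
        raise ParameterError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    labelled, n = ndimage.label(mask.data > 0, structure=_STRUCTURES[connectivity])
    if n == 0:
        warnings.warn("largest_component: mask is empty", stacklevel=2)
        return mask.replace(data=np.zeros_like(mask.data, dtype=np.uint8))
    counts = np.bincount(labelled.ravel())[1:]  # skip background
    best = int(np.argmax(counts)) + 1  # argmax -> smallest label on ties
    if np.count_nonzero(counts == counts[best - 1]) > 1:
        warnings.warn(
            "largest_component: size tie; keeping the smallest label",
            stacklevel=2,
        )
    return mask.replace(data=(labelled == best).astype(np.uint8))
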