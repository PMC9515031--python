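"""Femoral-head centre localization by multiplicative heatmap fusion.

The centre is found by predicting, slice by slice, a 2D heatmap per imaging
plane (axial and coronal), stacking each plane's predictions into a 3D
volume, multiplying the two volumes voxelwise, and taking the argmax. A 2D
prediction is ambiguous along its own stacking axis; the product of the two
orthogonal stacks resolves the ambiguity, so a Gaussian-shaped 3D heatmap
can be recovered from 2D predictors alone.

The slice predictors are a pluggable seam: the original system uses trained
2D U-Nets, which are not shipped here. Two reference predictors are
provided — an oracle that renders exact Gaussians around a known centre
(for verification) and a non-learned intensity-centroid predictor that
works on bright-ball images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np

from .errors import AlignmentError, LocalizationError, ParameterError
from .volumes import (
    AXIAL_DOWNSAMPLED,
    STANDARD_SIZE,
    ImageVolume,
    downsample_axial,
    require_same_geometry,
    resample_to_geometry,
    standardize_size,
)

__all__ = [
    "Heatmap3D",
    "SlicePredictor",
    "GaussianOraclePredictor",
    "CentroidSlicePredictor",
    "PREDICTORS",
    "register_predictor",
    "gaussian_heatmap",
    "predict_stack",
    "fuse_plane_heatmaps",
    "locate_centre",
    "localization_error",
]


@dataclass
class Heatmap3D(ImageVolume):
    """Scalar heatmap in [0, 1] on an :class:`ImageVolume` grid."""

    sigma: float | None = None

    def __post_init__(self):
        super().__post_init__()
        if self.data.size and (self.data.min() < -1e-9 or self.data.max() > 1 + 1e-9):
            raise ParameterError("heatmap values must lie in [0, 1]")


class SlicePredictor(Protocol):
    """Given a 2D slice image, return a 2D heatmap of the same shape in [0,1]."""

    def __call__(self, slice2d: np.ndarray) -> np.ndarray: ...


def gaussian_heatmap(geometry: ImageVolume, centre, sigma: float) -> Heatmap3D:
    """Gaussian of the world distance to ``centre``: exp(-|p-c|^2 / 2σ^2).

    Evaluated at voxel-centre world points, so iso-value surfaces are
    spheres in millimetres regardless of voxel anisotropy.
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    centre = np.asarray(centre, dtype=float).reshape(3)
    xs, ys, zs = geometry.axis_world_coords()
    d2 = (
        ((xs - centre[0]) ** 2)[:, None, None]
        + ((ys - centre[1]) ** 2)[None, :, None]
        + ((zs - centre[2]) ** 2)[None, None, :]
    )
    return Heatmap3D(
        data=np.exp(-d2 / (2.0 * sigma**2)),
        spacing=geometry.spacing,
        origin=geometry.origin,
        orientation=geometry.orientation,
        sigma=float(sigma),
    )


def _gauss2d(shape, centre_px, sigma_px) -> np.ndarray:
    ii = (np.arange(shape[0]) - centre_px[0])[:, None] / sigma_px[0]
    jj = (np.arange(shape[1]) - centre_px[1])[None, :] / sigma_px[1]
    return np.exp(-0.5 * (ii**2 + jj**2))


class GaussianOraclePredictor:
    """Oracle predictor: exact in-plane Gaussian at a known world centre.

    Stands in for a trained plane network in end-to-end tests. The in-plane
    pixel location of the centre and the mm->pixel conversion are captured
    from the grid the slices will be taken from.
    """

    def __init__(self, geometry: ImageVolume, centre_world, sigma_mm: float,
                 plane: str):
        if plane not in ("axial", "coronal"):
            raise ParameterError("plane must be 'axial' or 'coronal'")
        idx = geometry.world_to_index(np.asarray(centre_world, dtype=float))
        axes = (0, 1) if plane == "axial" else (0, 2)
        self._centre_px = idx[list(axes)]
        self._sigma_px = sigma_mm / geometry.spacing[list(axes)]

    def __call__(self, slice2d: np.ndarray) -> np.ndarray:
        return _gauss2d(slice2d.shape, self._centre_px, self._sigma_px)


class CentroidSlicePredictor:
    """Non-learned predictor: Gaussian around the intensity-weighted centroid.

    Works on bright-structure images such as the head phantom; blank slices
    yield an all-zero heatmap.
    """

    def __init__(self, in_plane_spacing, sigma_mm: float = 10.0):
        self._sigma_px = sigma_mm / np.asarray(in_plane_spacing, dtype=float)

    def __call__(self, slice2d: np.ndarray) -> np.ndarray:
        total = slice2d.sum()
        if total <= 0:
            return np.zeros_like(slice2d, dtype=float)
        ii, jj = np.indices(slice2d.shape)
        ci = (ii * slice2d).sum() / total
        cj = (jj * slice2d).sum() / total
        return _gauss2d(slice2d.shape, (ci, cj), self._sigma_px)


#: Plug-in registry for predictor factories, keyed by name.
PREDICTORS: dict[str, Callable] = {
    "gaussian_oracle": GaussianOraclePredictor,
    "centroid": CentroidSlicePredictor,
}


def register_predictor(name: str, factory: Callable) -> None:
    PREDICTORS[name] = factory


def predict_stack(vol: ImageVolume, predictor: SlicePredictor, plane: str) -> Heatmap3D:
    """Run a per-slice predictor over all slices of one plane and stack."""
    out = np.zeros(vol.shape, dtype=float)
    if plane == "axial":  # slices of constant S
        for k in range(vol.shape[2]):
            out[:, :, k] = predictor(vol.data[:, :, k])
    elif plane == "coronal":  # slices of constant P
        for j in range(vol.shape[1]):
            out[:, j, :] = predictor(vol.data[:, j, :])
    else:
        raise ParameterError("plane must be 'axial' or 'coronal'")
    return Heatmap3D(
        data=np.clip(out, 0.0, 1.0),
        spacing=vol.spacing,
        origin=vol.origin,
        orientation=vol.orientation,
    )


def fuse_plane_heatmaps(axial_stack: Heatmap3D, coronal_stack: Heatmap3D) -> Heatmap3D:
    """Voxelwise product of the two plane stacks (commutative, monotone)."""
    try:
        require_same_geometry(axial_stack, coronal_stack)
    except AlignmentError:
        raise AlignmentError("plane heatmap stacks do not share geometry") from None
    return Heatmap3D(
        data=axial_stack.data * coronal_stack.data,
        spacing=axial_stack.spacing,
        origin=axial_stack.origin,
        orientation=axial_stack.orientation,
    )


def _argmax_world(hm: Heatmap3D) -> np.ndarray:
    peak = hm.data.max()
    if peak <= 0:
        raise LocalizationError("fused heatmap is all zero; localization failed")
    flat = np.argmax(hm.data)  # first occurrence = lowest lexicographic index
    if np.count_nonzero(hm.data == peak) > 1:
        warnings.warn(
            "fused heatmap has tied maxima; taking the lowest index",
            stacklevel=3,
        )
    return hm.index_to_world(np.array(np.unravel_index(flat, hm.shape), dtype=float))


def locate_centre(
    morph_vol: ImageVolume,
    axial_predictor: SlicePredictor,
    coronal_predictor: SlicePredictor,
    standard_size: tuple | None = STANDARD_SIZE,
    axial_downsample: tuple | None = AXIAL_DOWNSAMPLED,
) -> np.ndarray:
    """Predict the femoral-head centre (world mm) on a morphological volume.

    Pipeline: optional size standardization; the axial path is optionally
    downsampled in-plane for speed, predicted, and linearly upsampled back
    onto the standardized grid; the coronal path is predicted at full
    resolution; the two stacks are fused by voxelwise multiplication and the
    argmax voxel's world coordinate is returned (ties -> lowest index, with
    a warning).
    """
    vol = morph_vol.canonicalized()
    if standard_size is not None:
        vol = standardize_size(vol, standard_size)
    if axial_downsample is not None:
        ax_in = downsample_axial(vol, axial_downsample)
        ax_hm = predict_stack(ax_in, axial_predictor, "axial")
        ax_hm_full = resample_to_geometry(ax_hm, vol, order=1)
        ax_hm = Heatmap3D(
            data=np.clip(ax_hm_full.data, 0.0, 1.0),
            spacing=vol.spacing,
            origin=vol.origin,
            orientation=vol.orientation,
        )
    else:
        ax_hm = predict_stack(vol, axial_predictor, "axial")
    cor_hm = predict_stack(vol, coronal_predictor, "coronal")
    fused = fuse_plane_heatmaps(ax_hm, cor_hm)
    return _argmax_world(fused)


def localization_error(pred, truth) -> float:
    """Euclidean distance (mm) between predicted and true centres."""
    pred = np.asarray(pred, dtype=float).reshape(3)
    truth = np.asarray(truth, dtype=float).reshape(3)
    return float(np.linalg.norm(pred - truth))
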