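"""2D (azimuth, inclination) surface maps of thickness and dGEMRIC.

Cartilage voxels are projected onto the unit sphere of the anatomical
frame: azimuth is the clock angle around Y (0 at 12 o'clock) and
inclination the polar angle from the cartilage-facing pole of Y. Within a
bin,

* the *thickness map* keeps the maximum local thickness (non-maximum
  suppression), where local thickness of a voxel is twice its world-metric
  distance to the nearest non-cartilage voxel (the distance map peaks at
  half the shell thickness on the medial surface);
* the *dGEMRIC map* is the radial average (mean T1) over the requested
  cartilage layer's voxels.

Bins with no projecting voxel are NaN (missing).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import AlignmentError, ParameterError
from .geometry import AnatomicalFrame, Sphere
from .sectioning import (
    LAYER_ACETABULAR,
    LAYER_FEMORAL,
    assign_layers,
    voxel_clock_angle,
    voxel_polar_angle,
)
from .volumes import ImageVolume, LabelVolume, same_geometry

__all__ = ["ProjectionMap", "thickness_map", "dgemric_map", "save_map"]

DEFAULT_BINS = (360, 180)  # 1-degree azimuth x inclination resolution


@dataclass
class ProjectionMap:
    """2D grid over (azimuth, inclination) with bin edges and units."""

    values: np.ndarray  # (n_azimuth, n_inclination), NaN = missing
    azimuth_edges: np.ndarray
    inclination_edges: np.ndarray
    units: str

    @property
    def bins(self) -> tuple:
        return self.values.shape

    def coverage(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def bin_solid_angles(self) -> np.ndarray:
        """Solid angle (sr) per bin, for area-weighted averaging."""
        daz = np.diff(np.radians(self.azimuth_edges))
        pol = np.radians(self.inclination_edges)
        dcos = np.cos(pol[:-1]) - np.cos(pol[1:])
        return daz[:, None] * dcos[None, :]


def _bin_indices(mask: LabelVolume, frame: AnatomicalFrame, bins):
    n_az, n_in = bins
    if n_az < 1 or n_in < 1:
        raise ParameterError(f"bins must be >= 1, got {bins}")
    fg = mask.data > 0
    theta = voxel_clock_angle(mask, frame)[fg]
    phi = voxel_polar_angle(mask, frame)[fg]
    az = np.minimum((theta / (360.0 / n_az)).astype(int), n_az - 1)
    inc = np.minimum((phi / (180.0 / n_in)).astype(int), n_in - 1)
    return fg, az, inc


def _edges(bins):
    n_az, n_in = bins
    return np.linspace(0, 360, n_az + 1), np.linspace(0, 180, n_in + 1)


def thickness_map(
    mask: LabelVolume,
    sphere: Sphere,
    frame: AnatomicalFrame,
    bins=DEFAULT_BINS,
) -> ProjectionMap:
    """Max local thickness (mm) per (azimuth, inclination) bin."""
    az_edges, in_edges = _edges(bins)
    values = np.full(bins, np.nan)
    if (mask.data > 0).any():
        # anisotropy-aware distance to the nearest background voxel centre,
        # corrected by half a voxel per side (the physical interface lies
        # about half a voxel inside the background centre), then doubled
        edt = ndimage.distance_transform_edt(mask.data > 0, sampling=mask.spacing)
        half = float(mask.spacing.min()) / 2.0
        local = 2.0 * np.maximum(edt - half, half)
        fg, az, inc = _bin_indices(mask, frame, bins)
        flat = np.full(bins[0] * bins[1], -np.inf)
        np.maximum.at(flat, az * bins[1] + inc, local[fg])
        values = np.where(np.isfinite(flat), flat, np.nan).reshape(bins)
    return ProjectionMap(values, az_edges, in_edges, units="mm")


def dgemric_map(
    t1_map: ImageVolume,
    mask: LabelVolume,
    sphere: Sphere,
    frame: AnatomicalFrame,
    bins=DEFAULT_BINS,
    layer: str = "both",
) -> ProjectionMap:
    """Radial-average T1 (ms) per bin for one cartilage layer or both."""
    if not same_geometry(t1_map, mask):
        raise AlignmentError("T1 map and mask do not share geometry")
    if layer not in ("femoral", "acetabular", "both"):
        raise ParameterError("layer must be 'femoral', 'acetabular' or 'both'")
    sel_mask = mask
    if layer != "both":
        layers = assign_layers(mask, sphere)
        want = LAYER_FEMORAL if layer == "femoral" else LAYER_ACETABULAR
        sel_mask = mask.replace(data=(layers.data == want).astype(np.uint8))
    az_edges, in_edges = _edges(bins)
    values = np.full(bins, np.nan)
    if (sel_mask.data > 0).any():
        fg, az, inc = _bin_indices(sel_mask, frame, bins)
        flat_idx = az * bins[1] + inc
        sums = np.zeros(bins[0] * bins[1])
        counts = np.zeros(bins[0] * bins[1])
        np.add.at(sums, flat_idx, t1_map.data[fg])
        np.add.at(counts, flat_idx, 1.0)
        with np.errstate(invalid="ignore"):
            values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        values = values.reshape(bins)
    return ProjectionMap(values, az_edges, in_edges, units="ms")


def save_map(pmap: ProjectionMap, path_png, sidecar_json=None) -> None:
    """Export a map as PNG plus a colour-bar sidecar JSON (min/max, units)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path_png = Path(path_png)
    finite = pmap.values[np.isfinite(pmap.values)]
    vmin = float(finite.min()) if finite.size else 0.0
    vmax = float(finite.max()) if finite.size else 0.0
    plt.imsave(
        path_png,
        np.nan_to_num(pmap.values.T, nan=vmin),
        vmin=vmin,
        vmax=vmax,
        cmap="viridis",
        origin="lower",
    )
    sidecar = Path(sidecar_json) if sidecar_json else path_png.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {"min": vmin, "max": vmax, "units": pmap.units, "bins": list(pmap.bins)},
            indent=2,
            sort_keys=True,
        )
    )
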