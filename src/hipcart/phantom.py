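"""Synthetic lunate cartilage-shell phantoms with exact analytic truth.

The hip cartilage is modelled as a patch of a spherical shell: voxels whose
distance to a known centre lies in ``[r_inner, r_outer]`` and whose polar
angle (from a symmetry axis, the anatomical Y) and azimuth (measured from a
reference axis, the anatomical 12-o'clock Z) lie in stated bands. Real
lunate cartilage is more complex, but this shape carries every property the
pipeline measures — centre, radius, thickness, surface area, volume and a
known T1 field — in closed form, so phantoms stand in for patient MRI in
all tests.

The weight-bearing hip cartilage is only 3–4 mm thick on a femoral head of
roughly 45 mm radius; the defaults mirror that scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DomainError, ParameterError
from .volumes import ImageVolume, LabelVolume, write_volume

__all__ = ["PhantomTruth", "make_shell_phantom", "make_head_phantom", "save_phantom"]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ParameterError("axis must be a non-zero vector")
    return v / n


@dataclass
class PhantomTruth:
    """Analytic ground truth of a shell phantom.

    ``polar_range`` is measured in degrees from ``symmetry_axis`` (the true
    anatomical Y); ``azimuth_range`` in degrees around it, zero at
    ``reference_axis`` (the true 12-o'clock Z) increasing towards
    ``symmetry_axis x reference_axis``. Band membership is half-open
    ``[min, max)``; the full azimuth (0, 360) covers everything.
    """

    centre: np.ndarray = field(default_factory=lambda: np.zeros(3))
    r_inner: float = 42.5
    r_outer: float = 45.5
    symmetry_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    reference_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, -1.0, 0.0]))
    polar_range: tuple = (0.0, 180.0)
    azimuth_range: tuple = (0.0, 360.0)
    side: str = "right"
    t1_field: str = "constant 500 ms"

    def __post_init__(self):
        self.centre = np.asarray(self.centre, dtype=float).reshape(3)
        self.symmetry_axis = _unit(self.symmetry_axis)
        self.reference_axis = _unit(self.reference_axis)
        # make the reference axis exactly orthogonal to the symmetry axis
        z = self.reference_axis - (self.reference_axis @ self.symmetry_axis) * self.symmetry_axis
        if np.linalg.norm(z) < 1e-9:
            raise ParameterError("reference_axis parallel to symmetry_axis")
        self.reference_axis = _unit(z)
        if not 0 < self.r_inner < self.r_outer:
            raise ParameterError("need 0 < r_inner < r_outer")
        pmin, pmax = self.polar_range
        if not (0 <= pmin <= pmax <= 180):
            raise ParameterError("polar_range must satisfy 0 <= min <= max <= 180")

    # -- analytic quantities ----------------------------------------------
    @property
    def r_mid(self) -> float:
        return 0.5 * (self.r_inner + self.r_outer)

    @property
    def analytic_thickness(self) -> float:
        return self.r_outer - self.r_inner

    @property
    def solid_angle_fraction(self) -> float:
        """Fraction of the full sphere subtended by the angular bands."""
        pmin, pmax = np.radians(self.polar_range)
        az_frac = (self.azimuth_range[1] - self.azimuth_range[0]) / 360.0
        return az_frac * 0.5 * (np.cos(pmin) - np.cos(pmax))

    @property
    def analytic_area_midsphere(self) -> float:
        """Patch area on the mid-surface sphere, mm^2."""
        return self.solid_angle_fraction * 4.0 * np.pi * self.r_mid**2

    @property
    def analytic_volume(self) -> float:
        """Patch volume, mm^3."""
        return (
            self.solid_angle_fraction
            * (4.0 / 3.0)
            * np.pi
            * (self.r_outer**3 - self.r_inner**3)
        )

    def local_frame(self):
        """(X, Y, Z) of the truth frame: Y symmetry, Z reference, X = Y x Z."""
        y = self.symmetry_axis
        z = self.reference_axis
        return np.cross(y, z), y, z

    def to_dict(self) -> dict:
        return {
            "centre": self.centre.tolist(),
            "r_inner": self.r_inner,
            "r_outer": self.r_outer,
            "symmetry_axis": self.symmetry_axis.tolist(),
            "reference_axis": self.reference_axis.tolist(),
            "polar_range": list(self.polar_range),
            "azimuth_range": list(self.azimuth_range),
            "side": self.side,
            "t1_field": self.t1_field,
            "analytic_volume": self.analytic_volume,
            "analytic_area_midsphere": self.analytic_area_midsphere,
            "analytic_thickness": self.analytic_thickness,
        }


def _angular_fields(vol_shape, origin, spacing, truth):
    """Radius, polar angle (deg) and azimuth (deg) per voxel centre."""
    xs = origin[0] + np.arange(vol_shape[0]) * spacing[0]
    ys = origin[1] + np.arange(vol_shape[1]) * spacing[1]
    zs = origin[2] + np.arange(vol_shape[2]) * spacing[2]
    dx = (xs - truth.centre[0])[:, None, None]
    dy = (ys - truth.centre[1])[None, :, None]
    dz = (zs - truth.centre[2])[None, None, :]
    r = np.sqrt(dx**2 + dy**2 + dz**2)
    x_ax, y_ax, z_ax = truth.local_frame()

    def dot(ax):
        return dx * ax[0] + dy * ax[1] + dz * ax[2]

    with np.errstate(invalid="ignore", divide="ignore"):
        polar = np.degrees(np.arccos(np.clip(dot(y_ax) / np.where(r > 0, r, 1.0), -1, 1)))
    azim = np.degrees(np.arctan2(dot(x_ax), dot(z_ax))) % 360.0
    return r, polar, azim


def make_shell_phantom(
    truth: PhantomTruth | None = None,
    spacing=(1.0, 1.0, 1.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    t1: float = 500.0,
    margin_mm: float = 4.0,
    shape=None,
    origin=None,
):
    """Voxelize a shell phantom; returns ``(t1_map, cartilage_mask, truth)``.

    A voxel belongs to the cartilage iff its centre's radius lies in
    ``[r_inner, r_outer]`` (optionally jittered per angular bin by
    ``noise_sd`` mm, seeded) and its polar/azimuth angles lie in the truth's
    bands. The T1 map carries ``t1`` ms inside the mask, 0 outside.
    Deterministic for a fixed ``(truth, spacing, noise_sd, seed)``.
    """
    truth = truth or PhantomTruth()
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    if origin is None or shape is None:
        half = truth.r_outer + margin_mm
        shape = tuple(int(np.ceil(2 * half / s)) + 1 for s in spacing)
        origin = truth.centre - (np.asarray(shape) - 1) / 2 * spacing
    else:
        origin = np.asarray(origin, dtype=float).reshape(3)
        shape = tuple(int(s) for s in shape)
        extent_lo = origin
        extent_hi = origin + (np.asarray(shape) - 1) * spacing
        if np.any(truth.centre - truth.r_outer < extent_lo) or np.any(
            truth.centre + truth.r_outer > extent_hi
        ):
            raise DomainError("shell exceeds the requested grid")

    r, polar, azim = _angular_fields(shape, origin, spacing, truth)

    r_in = np.full_like(r, truth.r_inner)
    r_out = np.full_like(r, truth.r_outer)
    if noise_sd > 0:
        # jitter the surfaces per 2-degree angular bin, reproducibly
        rng = np.random.default_rng(seed)
        npol, nazi = 90, 180
        jit_in = rng.normal(0.0, noise_sd, size=(npol, nazi))
        jit_out = rng.normal(0.0, noise_sd, size=(npol, nazi))
        pb = np.clip((polar / 2.0).astype(int), 0, npol - 1)
        ab = np.clip((azim / 2.0).astype(int), 0, nazi - 1)
        r_in = r_in + jit_in[pb, ab]
        r_out = r_out + jit_out[pb, ab]

    pmin, pmax = truth.polar_range
    amin, amax = truth.azimuth_range
    mask = (r >= r_in) & (r <= r_out)
    if (pmin, pmax) != (0.0, 180.0):
        mask &= (polar >= pmin) & (polar < pmax)
    if (amax - amin) < 360.0:
        a = (azim - amin) % 360.0
        mask &= a < (amax - amin)

    mask = mask.astype(np.uint8)
    t1_map = ImageVolume(
        data=np.where(mask > 0, float(t1), 0.0), spacing=spacing, origin=origin
    )
    label = LabelVolume(data=mask, spacing=spacing, origin=origin)
    return t1_map, label, truth


def make_head_phantom(centre, radius, spacing=(1.0, 1.0, 1.0), margin_mm=8.0,
                      intensity=1000.0, shape=None, origin=None) -> ImageVolume:
    """Bright ball on a dark background, mimicking the femoral head."""
    centre = np.asarray(centre, dtype=float).reshape(3)
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    if radius < 0:
        raise ParameterError("radius must be non-negative")
    if origin is None or shape is None:
        half = radius + margin_mm
        shape = tuple(int(np.ceil(2 * half / s)) + 1 for s in spacing)
        origin = centre - (np.asarray(shape) - 1) / 2 * spacing
    else:
        origin = np.asarray(origin, dtype=float).reshape(3)
        shape = tuple(int(s) for s in shape)
        if np.any(centre - radius < origin) or np.any(
            centre + radius > origin + (np.asarray(shape) - 1) * spacing
        ):
            raise DomainError("ball exceeds the requested grid")
    xs = origin[0] + np.arange(shape[0]) * spacing[0]
    ys = origin[1] + np.arange(shape[1]) * spacing[1]
    zs = origin[2] + np.arange(shape[2]) * spacing[2]
    r2 = (
        ((xs - centre[0]) ** 2)[:, None, None]
        + ((ys - centre[1]) ** 2)[None, :, None]
        + ((zs - centre[2]) ** 2)[None, None, :]
    )
    data = np.where(r2 <= radius**2, float(intensity), 0.0)
    if radius == 0 or not data.any():
        # degenerate ball: light the single nearest grid point
        data = np.zeros(shape)
        idx = np.unravel_index(np.argmin(r2), shape)
        data[idx] = float(intensity)
    return ImageVolume(data=data, spacing=spacing, origin=origin)


def save_phantom(t1_map, mask, truth, prefix) -> dict:
    """Write the NIfTI pair plus a JSON truth sidecar; returns the paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "t1": prefix.with_name(prefix.name + "_t1.nii"),
        "mask": prefix.with_name(prefix.name + "_mask.nii"),
        "truth": prefix.with_name(prefix.name + "_truth.json"),
    }
    write_volume(t1_map, paths["t1"])
    write_volume(mask, paths["mask"])
    paths["truth"].write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))
    return paths
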