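"""Clock-face / layer / region sectioning of the cartilage.

Every cartilage voxel is assigned to

* a *clock-face sector*: the angle θ = atan2(d·X, d·Z) around the symmetry
  axis Y, with θ = 0 at 12 o'clock (the Z axis) and θ = 90° at 3 o'clock
  (anterior), split into ``n_sectors`` equal half-open wedges;
* a *layer*: femoral if the voxel lies inside the fitted mid-layer sphere,
  acetabular if at or outside it (the layers are indistinct on non-traction
  MRI, so the fitted sphere splits the cartilage along its midline);
* a *region*: central if the polar angle from the cartilage-facing pole of
  Y is below a cone half-angle, else peripheral. ``"auto"`` picks the
  median polar angle, splitting the cartilage volume roughly in half.

Label maps use 0 for background. Sector k is stored as k+1; layers as
1 = femoral, 2 = acetabular; regions as 1 = central, 2 = peripheral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .geometry import AnatomicalFrame, Sphere
from .volumes import LabelVolume

__all__ = [
    "SectionLabeling",
    "assign_sectors",
    "assign_layers",
    "assign_regions",
    "section_label",
    "sector_clock_label",
    "clock_offset_from_landmark",
    "LAYER_FEMORAL",
    "LAYER_ACETABULAR",
    "REGION_CENTRAL",
    "REGION_PERIPHERAL",
]

LAYER_FEMORAL, LAYER_ACETABULAR = 1, 2
REGION_CENTRAL, REGION_PERIPHERAL = 1, 2


@dataclass
class SectionLabeling:
    """Per-voxel section assignment (sector, layer, region label volumes)."""

    sector: LabelVolume
    layer: LabelVolume | None
    region: LabelVolume | None
    n_sectors: int
    clock_offset_deg: float = 0.0
    cone_half_angle_deg: float | None = None

    @property
    def enabled(self) -> dict:
        return {"layers": self.layer is not None, "regions": self.region is not None}


def _relative_coords(mask: LabelVolume, origin):
    """d = p - origin for every voxel centre, as three broadcastable arrays."""
    xs, ys, zs = mask.axis_world_coords()
    return (
        (xs - origin[0])[:, None, None],
        (ys - origin[1])[None, :, None],
        (zs - origin[2])[None, None, :],
    )


def _dot(d, axis):
    dx, dy, dz = d
    return dx * axis[0] + dy * axis[1] + dz * axis[2]


def voxel_clock_angle(mask: LabelVolume, frame: AnatomicalFrame) -> np.ndarray:
    """θ in [0, 360) per voxel: 0 at 12 o'clock (Z), 90° at 3 o'clock (X)."""
    d = _relative_coords(mask, frame.origin)
    return np.degrees(np.arctan2(_dot(d, frame.X), _dot(d, frame.Z))) % 360.0


def assign_sectors(
    mask: LabelVolume,
    frame: AnatomicalFrame,
    n_sectors: int,
    clock_offset_deg: float = 0.0,
) -> LabelVolume:
    """Assign each cartilage voxel to one of ``n_sectors`` equal wedges.

    Sectors are half-open ``[a, b)`` starting at 12 o'clock; ties at a
    boundary fall into the higher-index sector. Sector k is labelled k+1.
    """
    if n_sectors < 1:
        raise ParameterError(f"n_sectors must be >= 1, got {n_sectors}")
    theta = (voxel_clock_angle(mask, frame) + clock_offset_deg) % 360.0
    sector = np.floor(theta / (360.0 / n_sectors)).astype(np.int32) % n_sectors
    out = np.where(mask.data > 0, sector + 1, 0).astype(np.int32)
    return mask.replace(data=out)


def assign_layers(mask: LabelVolume, sphere: Sphere) -> LabelVolume:
    """Split at the fitted mid-layer sphere: ρ < r femoral, ρ >= r acetabular."""
    d = _relative_coords(mask, sphere.centre)
    rho = np.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
    layer = np.where(rho < sphere.radius, LAYER_FEMORAL, LAYER_ACETABULAR)
    return mask.replace(data=np.where(mask.data > 0, layer, 0).astype(np.int32))


def oriented_pole(mask: LabelVolume, frame: AnatomicalFrame) -> np.ndarray:
    """Y oriented so the cartilage lies, on average, on its positive side."""
    d = _relative_coords(mask, frame.origin)
    dy = _dot(d, frame.Y)
    mean = dy[mask.data > 0].mean() if (mask.data > 0).any() else 0.0
    return frame.Y if mean >= 0 else -frame.Y


def voxel_polar_angle(mask: LabelVolume, frame: AnatomicalFrame) -> np.ndarray:
    """Polar angle (deg) of each voxel from the cartilage-facing pole of Y."""
    pole = oriented_pole(mask, frame)
    d = _relative_coords(mask, frame.origin)
    rho = np.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosphi = np.clip(_dot(d, pole) / np.where(rho > 0, rho, 1.0), -1.0, 1.0)
    return np.degrees(np.arccos(cosphi))


def assign_regions(
    mask: LabelVolume, frame: AnatomicalFrame, cone_half_angle="auto"
):
    """Central/peripheral split by a cone along Y with tip at the centre.

    Returns ``(region_labels, cone_half_angle_deg)``; ``"auto"`` uses the
    cartilage's median polar angle (≈ 50/50 volume split).
    """
    phi = voxel_polar_angle(mask, frame)
    fg = mask.data > 0
    if cone_half_angle == "auto":
        cone_half_angle = float(np.median(phi[fg])) if fg.any() else 90.0
    cone_half_angle = float(cone_half_angle)
    region = np.where(phi < cone_half_angle, REGION_CENTRAL, REGION_PERIPHERAL)
    out = mask.replace(data=np.where(fg, region, 0).astype(np.int32))
    return out, cone_half_angle


def section_label(
    mask: LabelVolume,
    frame: AnatomicalFrame,
    sphere: Sphere,
    n_sectors: int = 4,
    layers: bool = True,
    regions: bool = True,
    cone_half_angle="auto",
    clock_offset_deg: float = 0.0,
) -> SectionLabeling:
    """Full sectioning: sectors plus optional layers and regions."""
    sector = assign_sectors(mask, frame, n_sectors, clock_offset_deg)
    layer = assign_layers(mask, sphere) if layers else None
    region = None
    cone = None
    if regions:
        region, cone = assign_regions(mask, frame, cone_half_angle)
    return SectionLabeling(
        sector=sector,
        layer=layer,
        region=region,
        n_sectors=n_sectors,
        clock_offset_deg=clock_offset_deg,
        cone_half_angle_deg=cone,
    )


def sector_clock_label(k: int, n_sectors: int) -> str:
    """Clock-hour span of sector k, e.g. n=4, k=0 -> ``"12-3"``."""

    def hour(h: float) -> str:
        h = h % 12.0
        if h == 0:
            return "12"
        return f"{h:g}"

    start = k * 12.0 / n_sectors
    end = (k + 1) * 12.0 / n_sectors
    return f"{hour(start)}-{hour(end)}"


def clock_offset_from_landmark(frame: AnatomicalFrame, landmark_world) -> float:
    """Offset (deg) anchoring a 6-o'clock landmark (e.g. acetabular teardrop).

    Returns the ``clock_offset_deg`` that maps the landmark's clock angle to
    180°, re-anchoring the clock face on a user-picked landmark.
    """
    d = np.asarray(landmark_world, dtype=float) - frame.origin
    theta = np.degrees(np.arctan2(d @ frame.X, d @ frame.Z)) % 360.0
    return (180.0 - theta) % 360.0
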