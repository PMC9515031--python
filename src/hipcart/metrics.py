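"""Per-section cartilage quality metrics and segmentation evaluation.

For each cartilage section the tool reports

* dGEMRIC index — the mean T1_GD (ms) over the section's voxels;
* volume — voxel count x voxel volume (mm^3);
* surface area — a load-surface measure robust to voxel size and edge
  effects: the fitted sphere is represented by N near-equidistant points
  (a Fibonacci lattice, N = 100 000 by default); each point searches ±2 mm
  radially for cartilage and, if it hits, is assigned to the section of the
  hit nearest the fitted radius. The section area is then
  ``S_section = N_section / N * 4 pi r^2``;
* thickness — section volume divided by section surface area (mm).

Segmentation evaluation provides the Dice similarity coefficient, the
(true maximum) Hausdorff distance, and the average surface distance, all on
boundary-voxel world coordinates in mm.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import AlignmentError, DomainError, ParameterError
from .geometry import Sphere
from .sectioning import SectionLabeling, sector_clock_label
from .volumes import ImageVolume, LabelVolume, same_geometry

__all__ = [
    "dgemric_index",
    "section_volume",
    "generate_sphere_points",
    "surface_point_sections",
    "section_surface_area",
    "section_thickness",
    "dice",
    "hausdorff",
    "avg_surface_distance",
    "build_section_report",
]

DEFAULT_N_POINTS = 100_000
DEFAULT_SEARCH_MM = 2.0

_LAYER_NAMES = {1: "femoral", 2: "acetabular"}
_REGION_NAMES = {1: "central", 2: "peripheral"}


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, LabelVolume):
        return mask.data > 0
    return np.asarray(mask) > 0


def dgemric_index(t1_map: ImageVolume, section_mask) -> float:
    """Mean T1_GD (ms) over the section's voxels; NaN if the section is empty."""
    sel = _as_bool(section_mask)
    if sel.shape != t1_map.shape:
        raise AlignmentError("section mask does not match the T1 map grid")
    if not sel.any():
        warnings.warn("dgemric_index: empty section, reporting missing", stacklevel=2)
        return float("nan")
    return float(t1_map.data[sel].mean())


def section_volume(section_mask, spacing) -> float:
    """Voxel count x voxel volume, mm^3."""
    spacing = np.asarray(spacing, dtype=float)
    return float(np.count_nonzero(_as_bool(section_mask)) * np.prod(spacing))


def section_thickness(volume_mm3: float, surface_mm2: float) -> float:
    """Mean thickness = volume / surface area (mm); NaN for zero surface."""
    if surface_mm2 <= 0:
        warnings.warn("section_thickness: zero surface area", stacklevel=2)
        return float("nan")
    return volume_mm3 / surface_mm2


# ---------------------------------------------------------------------------
# surface area (sphere point sampling)
# ---------------------------------------------------------------------------

def generate_sphere_points(n: int) -> np.ndarray:
    """N near-equidistant unit vectors via the offset Fibonacci lattice.

    Deterministic. The degenerate n = 1 case returns the +pole.
    """
    if n < 1:
        raise ParameterError(f"need n >= 1, got {n}")
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(theta), s * np.sin(theta), z])


def surface_point_sections(
    mask: LabelVolume,
    labeling: SectionLabeling | None,
    sphere: Sphere,
    points: np.ndarray | None = None,
    n_points: int = DEFAULT_N_POINTS,
    search_mm: float = DEFAULT_SEARCH_MM,
    step_mm: float | None = None,
):
    """Assign sphere points to cartilage sections by radial search.

    For each unit direction u, the ray ``centre + t u`` is sampled at
    sub-voxel steps for ``t`` in ``[r - search_mm, r + search_mm]``; if any
    sample lands on cartilage, the point is assigned the (sector, layer,
    region) labels of the hit nearest the fitted radius. Points with no hit
    are unassigned.

    Returns ``(assigned, sections)`` where ``assigned`` is a boolean (N,)
    array and ``sections`` an (N, 3) int array of (sector, layer, region)
    labels (0 where unassigned or the dimension is disabled).
    """
    if points is None:
        points = generate_sphere_points(n_points)
    n = len(points)
    if step_mm is None:
        step_mm = float(mask.spacing.min()) / 2.0
    n_steps = max(1, int(np.ceil(2.0 * search_mm / step_mm))) + 1
    ts = np.linspace(sphere.radius - search_mm, sphere.radius + search_mm, n_steps)
    order = np.argsort(np.abs(ts - sphere.radius), kind="stable")
    ts = ts[order]  # nearest-to-r first, so the first hit wins

    shape = np.asarray(mask.shape)
    data = mask.data > 0
    sec = labeling.sector.data if labeling is not None else None
    lay = labeling.layer.data if (labeling and labeling.layer is not None) else None
    reg = labeling.region.data if (labeling and labeling.region is not None) else None

    assigned = np.zeros(n, dtype=bool)
    sections = np.zeros((n, 3), dtype=np.int32)
    # world -> nearest voxel index, canonical grid: (p - origin)/spacing
    for t in ts:
        remaining = ~assigned
        if not remaining.any():
            break
        p = sphere.centre + t * points[remaining]
        idx = np.rint((p - mask.origin) / mask.spacing).astype(np.int64)
        inb = np.all((idx >= 0) & (idx < shape), axis=1)
        if not inb.any():
            continue
        ii = idx[inb]
        hit = data[ii[:, 0], ii[:, 1], ii[:, 2]]
        rows = np.flatnonzero(remaining)[inb][hit]
        if rows.size == 0:
            continue
        hi = ii[hit]
        assigned[rows] = True
        if sec is not None:
            sections[rows, 0] = sec[hi[:, 0], hi[:, 1], hi[:, 2]]
        else:
            sections[rows, 0] = 1
        if lay is not None:
            sections[rows, 1] = lay[hi[:, 0], hi[:, 1], hi[:, 2]]
        if reg is not None:
            sections[rows, 2] = reg[hi[:, 0], hi[:, 1], hi[:, 2]]
    if not assigned.any():
        warnings.warn(
            "surface area: no sphere point hit the cartilage; degenerate geometry",
            stacklevel=2,
        )
    return assigned, sections


def section_surface_area(
    mask: LabelVolume,
    labeling: SectionLabeling | None,
    sphere: Sphere,
    points: np.ndarray | None = None,
    n_points: int = DEFAULT_N_POINTS,
    search_mm: float = DEFAULT_SEARCH_MM,
    step_mm: float | None = None,
) -> dict:
    """Surface area per (sector, layer, region) triple plus ``"total"``.

    Each area is ``N_section / N * 4 pi r^2`` (mm^2).
    """
    if points is None:
        points = generate_sphere_points(n_points)
    assigned, sections = surface_point_sections(
        mask, labeling, sphere, points=points, search_mm=search_mm, step_mm=step_mm
    )
    full = 4.0 * np.pi * sphere.radius**2
    n = len(points)
    areas: dict = {"total": assigned.sum() / n * full}
    keys, counts = np.unique(sections[assigned], axis=0, return_counts=True)
    for key, cnt in zip(keys, counts):
        areas[tuple(int(v) for v in key)] = cnt / n * full
    return areas


# ---------------------------------------------------------------------------
# segmentation evaluation
# ---------------------------------------------------------------------------

def dice(a: LabelVolume, b: LabelVolume) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|); 1.0 if both empty."""
    if not same_geometry(a, b):
        raise AlignmentError("masks do not share geometry")
    am, bm = a.data > 0, b.data > 0
    denom = am.sum() + bm.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(am, bm).sum() / denom)


def _boundary_points(mask: LabelVolume) -> np.ndarray:
    fg = mask.data > 0
    if not fg.any():
        raise DomainError("mask is empty; surface distances undefined")
    eroded = ndimage.binary_erosion(fg, ndimage.generate_binary_structure(3, 1))
    boundary = fg & ~eroded
    return mask.index_to_world(np.argwhere(boundary).astype(float))


def _directed_dists(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    d, _ = cKDTree(pb).query(pa, k=1)
    return d


def hausdorff(a: LabelVolume, b: LabelVolume) -> float:
    """Symmetric Hausdorff distance (mm) between boundary voxel centres."""
    if not same_geometry(a, b):
        raise AlignmentError("masks do not share geometry")
    pa, pb = _boundary_points(a), _boundary_points(b)
    return float(max(_directed_dists(pa, pb).max(), _directed_dists(pb, pa).max()))


def avg_surface_distance(a: LabelVolume, b: LabelVolume) -> float:
    """Average surface distance (mm): mean of the two directed means."""
    if not same_geometry(a, b):
        raise AlignmentError("masks do not share geometry")
    pa, pb = _boundary_points(a), _boundary_points(b)
    return float(
        0.5 * (_directed_dists(pa, pb).mean() + _directed_dists(pb, pa).mean())
    )


# ---------------------------------------------------------------------------
# section report
# ---------------------------------------------------------------------------

def _row_mask(labeling: SectionLabeling, sector, layer, region) -> np.ndarray:
    sel = labeling.sector.data > 0
    if sector is not None:
        sel &= labeling.sector.data == sector
    if layer is not None:
        sel &= labeling.layer.data == layer
    if region is not None:
        sel &= labeling.region.data == region
    return sel


def _row_area(areas: dict, sector, layer, region) -> float:
    total = 0.0
    for key, val in areas.items():
        if key == "total":
            continue
        s, l, r = key
        if s == 0:
            continue  # unassigned
        if sector is not None and s != sector:
            continue
        if layer is not None and l != layer:
            continue
        if region is not None and r != region:
            continue
        total += val
    return total


def build_section_report(
    t1_map: ImageVolume,
    mask: LabelVolume,
    labeling: SectionLabeling,
    sphere: Sphere,
    n_points: int = DEFAULT_N_POINTS,
    search_mm: float = DEFAULT_SEARCH_MM,
    points: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-section report: dGEMRIC index, thickness, surface area, volume.

    Rows cover the finest enabled partition (sector x layer x region), the
    marginals of each enabled dimension, and an overall row. Empty sections
    report NaN for dGEMRIC and thickness (missing, not zero).
    """
    if not same_geometry(t1_map, mask):
        raise AlignmentError("T1 map and cartilage mask do not share geometry")
    areas = section_surface_area(
        mask, labeling, sphere, points=points, n_points=n_points, search_mm=search_mm
    )
    vv = mask.voxel_volume
    n_sectors = labeling.n_sectors
    layer_vals = [1, 2] if labeling.layer is not None else [None]
    region_vals = [1, 2] if labeling.region is not None else [None]
    sector_vals = list(range(1, n_sectors + 1))

    rows = []

    def add_row(kind, sector, layer, region):
        sel = _row_mask(labeling, sector, layer, region)
        count = int(sel.sum())
        vol = count * vv
        area = _row_area(areas, sector, layer, region)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dg = dgemric_index(t1_map, sel) if count else float("nan")
            th = section_thickness(vol, area) if area > 0 else float("nan")
        rows.append(
            {
                "row": kind,
                "sector": sector if sector is not None else "all",
                "clock": sector_clock_label(sector - 1, n_sectors)
                if sector is not None
                else "all",
                "layer": _LAYER_NAMES.get(layer, "all"),
                "region": _REGION_NAMES.get(region, "all"),
                "voxel_count": count,
                "volume_mm3": vol,
                "surface_mm2": area,
                "thickness_mm": th,
                "dgemric_ms": dg,
            }
        )

    add_row("overall", None, None, None)
    n_dims = 1 + (labeling.layer is not None) + (labeling.region is not None)
    if n_dims > 1:  # marginals per enabled dimension
        for s in sector_vals:
            add_row("sector_marginal", s, None, None)
        if labeling.layer is not None:
            for l in (1, 2):
                add_row("layer_marginal", None, l, None)
        if labeling.region is not None:
            for r in (1, 2):
                add_row("region_marginal", None, None, r)
    for s in sector_vals:
        for l in layer_vals:
            for r in region_vals:
                add_row("section", s, l, r)
    return pd.DataFrame(rows)
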