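"""Volume containers and geometric primitives.

All world quantities are in millimetres in the LPS (left, posterior,
superior) convention used for hip MRI. A volume is a 3D scalar grid with
per-axis voxel spacing, the world position of the centre of voxel (0,0,0),
and an orientation matrix whose columns map grid axes to world axes. The
world coordinate of voxel index ``i`` is ``origin + orientation @ (i * spacing)``.

A *canonical* volume has identity orientation, i.e. grid axes aligned with
+L, +P, +S. Every analysis routine in the package assumes canonical input;
:func:`read_volume` canonicalizes on load.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import (
    AlignmentError,
    DimensionalityError,
    DomainError,
    FormatError,
    ParameterError,
)

__all__ = [
    "ImageVolume",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "standardize_size",
    "crop_about_point",
    "downsample_axial",
    "resample_to_geometry",
    "same_geometry",
]

#: 4x4 change of basis between nibabel's RAS+ affines and LPS.
_RAS2LPS = np.diag([-1.0, -1.0, 1.0, 1.0])

#: Standardized grid used before femoral-head localization.
STANDARD_SIZE = (768, 672, 160)
#: In-plane size of the downsampled axial localization path.
AXIAL_DOWNSAMPLED = (384, 336)
#: Crop size around the femoral-head centre handed to the segmenter.
CROP_SIZE = (368, 368, 96)


@dataclass
class ImageVolume:
    """3D scalar grid with LPS world geometry.

    Parameters
    ----------
    data
        3D array of scalar values (arbitrary units; ms for T1 maps).
    spacing
        Per-axis voxel size in mm, strictly positive.
    origin
        World position (mm, LPS) of the centre of voxel (0, 0, 0).
    orientation
        3x3 matrix with orthonormal columns mapping grid axes to world axes.
        Identity for canonical volumes.
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got ndim={self.data.ndim}"
            )
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ParameterError(f"spacing must be positive, got {self.spacing}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(3, 3)
        if not np.allclose(
            self.orientation.T @ self.orientation, np.eye(3), atol=1e-6
        ):
            raise ParameterError("orientation must have orthonormal columns")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 index->LPS world affine (voxel-centre convention)."""
        a = np.eye(4)
        a[:3, :3] = self.orientation * self.spacing[np.newaxis, :]
        a[:3, 3] = self.origin
        return a

    def index_to_world(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return self.origin + (self.orientation @ (idx * self.spacing).T).T.reshape(
            idx.shape
        )

    def world_to_index(self, world) -> np.ndarray:
        world = np.asarray(world, dtype=float)
        rel = (self.orientation.T @ (world - self.origin).T).T
        return (rel / self.spacing).reshape(world.shape)

    def axis_world_coords(self):
        """1D world coordinates per grid axis (canonical volumes only)."""
        if not self.is_canonical:
            raise ParameterError("axis_world_coords requires a canonical volume")
        return tuple(
            self.origin[a] + np.arange(self.data.shape[a]) * self.spacing[a]
            for a in range(3)
        )

    @property
    def is_canonical(self) -> bool:
        return bool(np.allclose(self.orientation, np.eye(3), atol=1e-9))

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def replace(self, **kw) -> "ImageVolume":
        return dataclasses.replace(self, **kw)

    def canonicalized(self) -> "ImageVolume":
        """Reorder/flip grid axes so they align with +L, +P, +S.

        Requires the orientation to be a signed permutation (strict axial /
        coronal / sagittal acquisition). World coordinates of every voxel are
        preserved exactly.
        """
        if self.is_canonical:
            return self
        o = self.orientation
        if not np.allclose(np.abs(o), np.rint(np.abs(o)), atol=1e-6):
            raise FormatError(
                "oblique orientation; resample to strict axial planes first"
            )
        perm = np.zeros(3, dtype=int)  # perm[world_axis] = grid_axis
        signs = np.zeros(3)
        for j in range(3):
            a = int(np.argmax(np.abs(o[:, j])))
            perm[a] = j
            signs[a] = np.sign(o[a, j])
        data = np.transpose(self.data, axes=perm)
        corner = np.zeros(3)
        for a in range(3):
            if signs[a] < 0:
                data = np.flip(data, axis=a)
                corner[perm[a]] = self.data.shape[perm[a]] - 1
        new_origin = self.index_to_world(corner)
        return self.replace(
            data=np.ascontiguousarray(data),
            spacing=self.spacing[perm],
            origin=new_origin,
            orientation=np.eye(3),
        )


@dataclass
class LabelVolume(ImageVolume):
    """Integer-labelled grid sharing :class:`ImageVolume` geometry.

    Label 0 is background; labels are non-negative.
    """

    def __post_init__(self):
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.rint(self.data)):
                raise ParameterError("labels must be integers")
            self.data = np.rint(self.data).astype(np.int32)
        if self.data.size and self.data.min() < 0:
            raise ParameterError("labels must be non-negative")

    @property
    def labels(self) -> np.ndarray:
        return self.data


def same_geometry(a: ImageVolume, b: ImageVolume, atol: float = 1e-6) -> bool:
    return (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing, atol=atol)
        and np.allclose(a.origin, b.origin, atol=atol)
        and np.allclose(a.orientation, b.orientation, atol=atol)
    )


def require_same_geometry(*vols: ImageVolume) -> None:
    first = vols[0]
    for v in vols[1:]:
        if not same_geometry(first, v):
            raise AlignmentError("volumes do not share grid geometry")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _from_lps_affine(data: np.ndarray, affine_lps: np.ndarray, label: bool):
    m = affine_lps[:3, :3]
    spacing = np.linalg.norm(m, axis=0)
    if np.any(spacing <= 0):
        raise FormatError("affine has a zero-length axis")
    cls = LabelVolume if label else ImageVolume
    vol = cls(
        data=data,
        spacing=spacing,
        origin=affine_lps[:3, 3],
        orientation=m / spacing[np.newaxis, :],
    )
    return vol.canonicalized()


def read_volume(path, format: str = "nifti", label: bool = False):
    """Read a 3D volume and return it in canonical LPS orientation.

    Parameters
    ----------
    path
        File path (NIfTI) or directory (DICOM series).
    format
        ``"nifti"`` or ``"dicom_series"``.
    label
        Return a :class:`LabelVolume` instead of an :class:`ImageVolume`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "nifti":
        try:
            img = nib.load(str(path))
        except Exception as exc:  # nibabel raises a zoo of error types
            raise FormatError(f"cannot read NIfTI {path}: {exc}") from exc
        data = np.asarray(img.dataobj)
        if data.ndim != 3:
            raise DimensionalityError(
                f"expected 3D data, file has shape {data.shape}"
            )
        affine_lps = _RAS2LPS @ img.affine
        return _from_lps_affine(data, affine_lps, label)
    if format == "dicom_series":
        return _read_dicom_series(path, label)
    raise ParameterError(f"unknown format {format!r}")


def _read_dicom_series(directory: Path, label: bool):
    # Convenience path; NIfTI is the reference format. ITK is LPS-native.
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(directory))
    if not files:
        raise FormatError(f"no DICOM series found in {directory}")
    reader.SetFileNames(files)
    img = reader.Execute()
    if img.GetDimension() != 3:
        raise DimensionalityError("DICOM series is not a 3D volume")
    data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    affine = np.eye(4)
    d = np.asarray(img.GetDirection()).reshape(3, 3)
    affine[:3, :3] = d * np.asarray(img.GetSpacing())[np.newaxis, :]
    affine[:3, 3] = img.GetOrigin()
    return _from_lps_affine(data, affine, label)


def write_volume(vol: ImageVolume, path, format: str = "nifti") -> Path:
    """Write a volume as NIfTI-1 with lossless geometry."""
    if format != "nifti":
        raise ParameterError("only NIfTI output is supported")
    path = Path(path)
    affine_ras = _RAS2LPS @ vol.affine
    img = nib.Nifti1Image(vol.data, affine_ras)
    img.set_qform(affine_ras, code=1)
    img.set_sform(affine_ras, code=1)
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# Grid manipulation
# ---------------------------------------------------------------------------

def _background_value(vol: ImageVolume, background):
    if background is not None:
        return background
    if isinstance(vol, LabelVolume):
        return 0
    return vol.data.min() if vol.data.size else 0


def standardize_size(vol: ImageVolume, target=STANDARD_SIZE, background=None):
    """Symmetric pad / centre-crop each axis to ``target`` voxels.

    Retained voxels keep their world coordinates; the origin moves with the
    pad/crop. Padding uses ``background`` (default: 0 for labels, the volume
    minimum for images).
    """
    if not vol.is_canonical:
        raise ParameterError("standardize_size requires a canonical volume")
    bg = _background_value(vol, background)
    start = np.zeros(3)  # index of output voxel (0,0,0) in input index space
    pads, slices = [], []
    for a, (n, t) in enumerate(zip(vol.shape, target)):
        if n < t:
            lead = (t - n) // 2
            pads.append((lead, t - n - lead))
            slices.append(slice(None))
            start[a] = -lead
        else:
            lead = (n - t) // 2
            pads.append((0, 0))
            slices.append(slice(lead, lead + t))
            start[a] = lead
    data = vol.data[tuple(slices)]
    if any(p != (0, 0) for p in pads):
        data = np.pad(data, pads, constant_values=bg)
    return vol.replace(data=data, origin=vol.index_to_world(start))


def crop_about_point(vol: ImageVolume, centre, size=CROP_SIZE, background=None):
    """Crop a fixed-size grid whose central voxel is nearest ``centre`` (mm).

    Regions falling outside the input are background-filled so that the
    requested centre stays at the crop's central voxel.
    """
    if not vol.is_canonical:
        raise ParameterError("crop_about_point requires a canonical volume")
    idx_c = np.rint(vol.world_to_index(np.asarray(centre, dtype=float)))
    if np.any(idx_c < 0) or np.any(idx_c > np.asarray(vol.shape) - 1):
        raise DomainError(f"centre {centre} lies outside the volume")
    idx_c = idx_c.astype(int)
    size = np.asarray(size, dtype=int)
    start = idx_c - size // 2
    stop = start + size
    bg = _background_value(vol, background)
    out = np.full(tuple(size), bg, dtype=vol.data.dtype)
    src = tuple(
        slice(max(0, s), min(n, e)) for s, e, n in zip(start, stop, vol.shape)
    )
    dst = tuple(
        slice(max(0, -s), max(0, -s) + (sl.stop - sl.start))
        for s, sl in zip(start, src)
    )
    out[dst] = vol.data[src]
    return vol.replace(data=out, origin=vol.index_to_world(start.astype(float)))


def downsample_axial(vol: ImageVolume, target_in_plane=AXIAL_DOWNSAMPLED):
    """Downsample in-plane (axes L, P) by integer block averaging.

    Slice count is unchanged; in-plane spacing scales by the block factor and
    the origin moves to the mean world coordinate of each block's pixels.
    """
    if not vol.is_canonical:
        raise ParameterError("downsample_axial requires a canonical volume")
    nx, ny, nz = vol.shape
    tx, ty = target_in_plane
    if nx % tx or ny % ty:
        raise ParameterError(
            f"in-plane size {(nx, ny)} is not an integer multiple of {(tx, ty)}"
        )
    fx, fy = nx // tx, ny // ty
    data = (
        vol.data.astype(float)
        .reshape(tx, fx, ty, fy, nz)
        .mean(axis=(1, 3))
    )
    spacing = vol.spacing * np.array([fx, fy, 1.0])
    shift = np.array([(fx - 1) / 2, (fy - 1) / 2, 0.0])
    return ImageVolume(
        data=data,
        spacing=spacing,
        origin=vol.index_to_world(shift),
        orientation=vol.orientation,
    )


def resample_to_geometry(
    vol: ImageVolume, ref: ImageVolume, order: int = 1, background: float = 0.0
) -> ImageVolume:
    """Resample ``vol`` onto the grid of ``ref`` (linear by default)."""
    xs, ys, zs = ref.axis_world_coords()
    # canonical volumes: world->index is separable
    ix = (xs - vol.origin[0]) / vol.spacing[0]
    iy = (ys - vol.origin[1]) / vol.spacing[1]
    iz = (zs - vol.origin[2]) / vol.spacing[2]
    grid = np.meshgrid(ix, iy, iz, indexing="ij")
    data = ndimage.map_coordinates(
        vol.data.astype(float), grid, order=order, mode="constant", cval=background
    )
    return ImageVolume(
        data=data, spacing=ref.spacing, origin=ref.origin, orientation=ref.orientation
    )
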