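"""Femoral-head sphere fit and anatomical coordinate frame.

The femoral head centre and radius are recovered by an algebraic
least-squares sphere fit to the world coordinates of the segmented
cartilage voxels: expanding ``|p - c|^2 = r^2`` gives the linear system
``2 p . c + (r^2 - |c|^2) = |p|^2`` solved in closed form. Because the
cartilage shell straddles the head surface roughly symmetrically, the fit
lands on the cartilage mid-layer.

The anatomical frame anchors the clock face: Y is the cartilage's first
mechanical principal axis (the inertia-maximal, covariance-minimal
direction — the symmetry axis of the lunate patch), Z points from the
sphere centre towards the in-plane projection of the cartilage centroid
(12 o'clock), and X = Y x Z. Y's sign is chosen so that X points anterior,
making 3 o'clock anterior in both left and right hips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AmbiguityError, DomainError, FitError, FrameError
from .volumes import LabelVolume

__all__ = [
    "Sphere",
    "AnatomicalFrame",
    "fit_sphere",
    "cartilage_centroid",
    "principal_axis",
    "build_frame",
    "frame_from_mask",
]

#: Default anterior direction in LPS (-P).
ANTERIOR_LPS = np.array([0.0, -1.0, 0.0])


@dataclass
class Sphere:
    centre: np.ndarray
    radius: float

    def __post_init__(self):
        self.centre = np.asarray(self.centre, dtype=float).reshape(3)
        self.radius = float(self.radius)
        if self.radius <= 0:
            raise FitError(f"non-positive fitted radius {self.radius}")

    def to_dict(self) -> dict:
        return {"centre": self.centre.tolist(), "radius": self.radius}


@dataclass
class AnatomicalFrame:
    """Right-handed orthonormal frame at the femoral-head centre."""

    origin: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    side: str = "right"

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        for name in ("X", "Y", "Z"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        m = np.column_stack([self.X, self.Y, self.Z])
        if not np.allclose(m.T @ m, np.eye(3), atol=1e-9):
            raise FrameError("frame axes are not orthonormal")
        if not np.allclose(np.cross(self.Y, self.Z), self.X, atol=1e-9):
            raise FrameError("frame is not right-handed (X != Y x Z)")

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "X": self.X.tolist(),
            "Y": self.Y.tolist(),
            "Z": self.Z.tolist(),
            "side": self.side,
        }


def _foreground_points(mask: LabelVolume) -> np.ndarray:
    idx = np.argwhere(mask.data > 0)
    if idx.size == 0:
        raise DomainError("mask is empty")
    return mask.index_to_world(idx.astype(float))


def fit_sphere(mask_or_points, refine: bool = False) -> Sphere:
    """Algebraic least-squares sphere through foreground voxel centres.

    Parameters
    ----------
    mask_or_points
        Binary :class:`LabelVolume` or an (N, 3) array of world points (mm).
    refine
        Run one Gauss–Newton pass on the geometric residuals after the
        algebraic solve.
    """
    if isinstance(mask_or_points, LabelVolume):
        pts = _foreground_points(mask_or_points)
    else:
        pts = np.asarray(mask_or_points, dtype=float).reshape(-1, 3)
    if len(pts) < 4:
        raise FitError(f"need >= 4 points, got {len(pts)}")
    # centre the data for conditioning
    mean = pts.mean(axis=0)
    q = pts - mean
    a = np.column_stack([2.0 * q, np.ones(len(q))])
    b = np.einsum("ij,ij->i", q, q)
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 4:
        raise FitError("degenerate point configuration (coplanar or collinear)")
    centre = sol[:3]
    r2 = sol[3] + centre @ centre
    if r2 <= 0:
        raise FitError("sphere fit produced a non-positive radius")
    centre = centre + mean
    radius = float(np.sqrt(r2))
    if refine:
        for _ in range(1):
            d = pts - centre
            dist = np.linalg.norm(d, axis=1)
            ok = dist > 1e-12
            jac = np.column_stack([-d[ok] / dist[ok, None], -np.ones(ok.sum())])
            res = dist[ok] - radius
            upd, *_ = np.linalg.lstsq(jac, -res, rcond=None)
            centre = centre + upd[:3]
            radius = float(radius + upd[3])
    return Sphere(centre=centre, radius=radius)


def cartilage_centroid(mask: LabelVolume) -> np.ndarray:
    """Unweighted mean world coordinate of the foreground voxel centres."""
    return _foreground_points(mask).mean(axis=0)


def principal_axis(mask: LabelVolume, rel_tol: float = 1e-2) -> np.ndarray:
    """First mechanical principal axis of the cartilage (sign-ambiguous).

    Eigen-decomposition of the covariance of foreground world coordinates;
    returns the eigenvector of the *smallest* covariance eigenvalue, i.e.
    the axis of largest moment of inertia — the symmetry axis of a lunate
    band. Raises :class:`AmbiguityError` when the two smallest eigenvalues
    are closer than ``rel_tol`` relative to the largest.
    """
    pts = _foreground_points(mask)
    if len(pts) < 3:
        raise DomainError("need >= 3 foreground voxels for a principal axis")
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    gap = (evals[1] - evals[0]) / max(evals[2], 1e-30)
    if gap < rel_tol:
        raise AmbiguityError(
            "principal axis not unique: covariance eigenvalue gaps "
            f"{(evals[1] - evals[0]):.3g}, {(evals[2] - evals[1]):.3g} "
            f"(relative gap {gap:.3g} < {rel_tol})"
        )
    return evecs[:, 0]


def build_frame(
    sphere: Sphere,
    centroid,
    axis_y,
    side: str = "right",
    anterior_dir=ANTERIOR_LPS,
) -> AnatomicalFrame:
    """Construct the clock-face frame from sphere, centroid and Y axis.

    Z is the centroid direction projected perpendicular to Y (12 o'clock);
    X = Y x Z. If X opposes ``anterior_dir``, Y is negated and X recomputed
    so that 3 o'clock is anterior regardless of side.
    """
    centroid = np.asarray(centroid, dtype=float).reshape(3)
    y = np.asarray(axis_y, dtype=float).reshape(3)
    y = y / np.linalg.norm(y)
    d = centroid - sphere.centre
    z = d - (d @ y) * y
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise FrameError("centroid lies on the Y axis; 12 o'clock undefined")
    z = z / nz
    x = np.cross(y, z)
    anterior = np.asarray(anterior_dir, dtype=float)
    if x @ anterior < 0:
        y = -y
        x = np.cross(y, z)
    return AnatomicalFrame(origin=sphere.centre, X=x, Y=y, Z=z, side=side)


def frame_from_mask(
    mask: LabelVolume,
    side: str = "right",
    anterior_dir=ANTERIOR_LPS,
    refine_sphere: bool = False,
    rel_tol: float = 1e-2,
):
    """Fit sphere + centroid + principal axis and build the frame.

    Returns ``(sphere, frame)``.
    """
    sphere = fit_sphere(mask, refine=refine_sphere)
    centroid = cartilage_centroid(mask)
    y = principal_axis(mask, rel_tol=rel_tol)
    frame = build_frame(sphere, centroid, y, side=side, anterior_dir=anterior_dir)
    return sphere, frame
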