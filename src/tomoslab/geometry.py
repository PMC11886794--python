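"""Tilt geometry: the voxel-to-detector mapping behind every algorithm.

Single-axis convention: the tilt axis is y.  A positive tilt rotates the
specimen right-handedly about +y; at zero tilt the detector column
increases with volume x and drops z.  The pitch angle is a constant
specimen-mounting rotation about x applied *before* the tilt, and the
z-shift translates the reconstruction slab center along the beam axis
before any rotation ("tomogram positioning").  Continuous coordinates put
the center of an n-sample axis at (n - 1)/2 with 0-based indexing, which
keeps forward and adjoint operators symmetric under flips.

For a voxel at index (ix, iy, iz) with centered offsets
(dx, dy, dz) = (ix - cx, iy - cy, iz - cz), tilt angle theta and pitch
angle alpha, the detector coordinates are::

    p_col = dx*cos(theta) + dy*sin(alpha)*sin(theta)
            + (dz + zshift)*cos(alpha)*sin(theta) + c_col
    p_row = dy*cos(alpha) - (dz + zshift)*sin(alpha) + c_row

so ``p_row == iy`` exactly whenever alpha == 0 — the property that makes
the y-slab decomposition exact at zero pitch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryConfig",
    "ProjectionTransform",
    "DegenerateGeometryError",
    "build_transforms",
    "map_voxel",
    "required_halo",
]


class DegenerateGeometryError(ValueError):
    """Geometry at which the projection model breaks down (|tilt| >= 90 deg)."""


@dataclass(frozen=True)
class GeometryConfig:
    """User geometry: tilt-angle offset, pitch, z-shift and output thickness.

    Parameters
    ----------
    thickness_voxels : int
        nz of the output volume (>= 1).
    tilt_offset_deg : float
        Global offset added to every nominal tilt angle.
    pitch_deg : float
        Specimen rotation about the x-axis, |pitch| < 90.
    zshift_voxels : float
        Displacement of the reconstruction slab center along z, in voxels.
    """

    thickness_voxels: int
    tilt_offset_deg: float = 0.0
    pitch_deg: float = 0.0
    zshift_voxels: float = 0.0

    def __post_init__(self) -> None:
        if self.thickness_voxels < 1:
            raise ValueError("thickness_voxels must be >= 1")
        if not abs(self.pitch_deg) < 90.0:
            raise DegenerateGeometryError("|pitch_deg| must be < 90")
        for name in ("tilt_offset_deg", "pitch_deg", "zshift_voxels"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class ProjectionTransform:
    """Affine map from voxel indices to continuous detector coordinates.

    ``(p_col, p_row) = matrix @ (ix, iy, iz) + offset``.  ``angle_deg`` is
    the effective tilt (nominal + offset) the transform was built for.
    """

    matrix: np.ndarray  # (2, 3), rows = (col, row) coefficients
    offset: np.ndarray  # (2,)
    angle_deg: float

    def shifted(
        self, vol_origin: tuple[int, int, int], det_origin: tuple[float, float]
    ) -> "ProjectionTransform":
        """Re-express the map for a sub-volume / sub-detector.

        ``vol_origin`` is the global (z, y, x) index of the sub-volume's
        (0, 0, 0) voxel; ``det_origin`` the global (row, col) of the
        sub-detector's (0, 0) pixel.  Used by the slab engine.
        """
        oz, oy, ox = vol_origin
        orow, ocol = det_origin
        o = np.array([ox, oy, oz], dtype=np.float64)
        new_offset = self.matrix @ o + self.offset - np.array([ocol, orow])
        return ProjectionTransform(self.matrix, new_offset, self.angle_deg)


def build_transforms(
    angles_deg,
    geom: GeometryConfig,
    vol_shape: tuple[int, int, int],
    det_shape: tuple[int, int],
) -> list[ProjectionTransform]:
    """One :class:`ProjectionTransform` per effective tilt angle.

    ``vol_shape`` is (nz, ny, nx); ``det_shape`` is (n_rows, n_cols).
    Raises :class:`DegenerateGeometryError` when any effective tilt
    reaches 90 degrees.
    """
    nz, ny, nx = vol_shape
    nrow, ncol = det_shape
    if min(nz, ny, nx, nrow, ncol) < 1:
        raise ValueError("shapes must be positive")
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    c_col, c_row = (ncol - 1) / 2.0, (nrow - 1) / 2.0
    alpha = math.radians(geom.pitch_deg)
    ca, sa = math.cos(alpha), math.sin(alpha)
    s = geom.zshift_voxels

    out: list[ProjectionTransform] = []
    for ang in np.asarray(angles_deg, dtype=np.float64).ravel():
        eff = ang + geom.tilt_offset_deg
        if not math.isfinite(eff):
            raise ValueError("tilt angles must be finite")
        if abs(eff) >= 90.0:
            raise DegenerateGeometryError(
                f"effective tilt {eff:.3f} deg is outside (-90, 90)"
            )
        th = math.radians(eff)
        ct, st = math.cos(th), math.sin(th)
        # p_col = dx*ct + dy*sa*st + (dz+s)*ca*st + c_col
        # p_row = dy*ca - (dz+s)*sa + c_row
        m = np.array(
            [[ct, sa * st, ca * st],
             [0.0, ca, -sa]],
            dtype=np.float64,
        )
        off = np.array(
            [
                -cx * ct - cy * sa * st + (s - cz) * ca * st + c_col,
                -cy * ca - (s - cz) * sa + c_row,
            ],
            dtype=np.float64,
        )
        out.append(ProjectionTransform(matrix=m, offset=off, angle_deg=float(eff)))
    return out


def map_voxel(t: ProjectionTransform, ix: int, iy: int, iz: int) -> tuple[float, float]:
    """Continuous detector (p_col, p_row) of voxel (ix, iy, iz)."""
    v = np.array([ix, iy, iz], dtype=np.float64)
    p = t.matrix @ v + t.offset
    return float(p[0]), float(p[1])


def required_halo(geom: GeometryConfig) -> int:
    """Extra detector rows each y-slab must load so pitch leaves no voids.

    Zero at zero pitch (the projection then never couples y-rows).  For
    nonzero pitch the worst-case row displacement of a slab voxel is
    bounded by the z-extent of the slab (thickness/2 plus |z-shift|) times
    tan(pitch); one extra row covers the bilinear interpolation footprint.
    """
    if geom.pitch_deg == 0.0:
        return 0
    t = math.tan(math.radians(abs(geom.pitch_deg)))
    reach = (geom.thickness_voxels / 2.0 + abs(geom.zshift_voxels)) * t
    return int(math.ceil(reach + 1.0))
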