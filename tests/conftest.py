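"""Shared fixtures and independent oracles for the test suite.

The dense-matrix oracle here is built voxel by voxel from ``map_voxel``
with explicit Python loops — deliberately independent of the sparse
operator assembly inside the package.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from tomoslab.geometry import GeometryConfig, ProjectionTransform, build_transforms, map_voxel


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def dense_projection_matrix(
    transforms: list[ProjectionTransform],
    vol_shape: tuple[int, int, int],
    det_shape: tuple[int, int],
) -> np.ndarray:
    """Dense (n_angles*n_det, n_vox) system matrix from per-voxel mapping.

    Splats each voxel onto its 4 bilinear detector neighbours, exactly the
    contract of the forward projector, but assembled with scalar loops.
    """
    nz, ny, nx = vol_shape
    nrow, ncol = det_shape
    n_vox = nz * ny * nx
    n_det = nrow * ncol
    a = np.zeros((len(transforms) * n_det, n_vox))
    for k, t in enumerate(transforms):
        for iz in range(nz):
            for iy in range(ny):
                for ix in range(nx):
                    p_col, p_row = map_voxel(t, ix, iy, iz)
                    c0 = math.floor(p_col)
                    r0 = math.floor(p_row)
                    fc = p_col - c0
                    fr = p_row - r0
                    j = (iz * ny + iy) * nx + ix
                    for dr, dc, w in (
                        (0, 0, (1 - fr) * (1 - fc)),
                        (0, 1, (1 - fr) * fc),
                        (1, 0, fr * (1 - fc)),
                        (1, 1, fr * fc),
                    ):
                        r, c = r0 + dr, c0 + dc
                        if w > 0 and 0 <= r < nrow and 0 <= c < ncol:
                            a[k * n_det + r * ncol + c, j] += w
    return a


def weighted_pinv_solution(
    a: np.ndarray, b: np.ndarray, row_w: np.ndarray, col_w: np.ndarray
) -> np.ndarray:
    """Weighted least-squares solution via a dense pseudo-inverse.

    Solves the normalized system R^(1/2) A C^(1/2) u = R^(1/2) b and maps
    back x = C^(1/2) u, i.e. the fixed point the normalized simultaneous
    iteration converges to from a zero start.
    """
    ri = np.divide(1.0, np.sqrt(row_w), out=np.zeros_like(row_w), where=row_w > 0)
    ci = np.divide(1.0, np.sqrt(col_w), out=np.zeros_like(col_w), where=col_w > 0)
    bmat = (ri[:, None] * a) * ci[None, :]
    return ci * (np.linalg.pinv(bmat) @ (ri * b))


@pytest.fixture
def tiny_geometry():
    """A small 3D problem: 9^3 volume, 5 angles across the wedge."""
    shape = (9, 9, 9)
    det = (9, 9)
    geom = GeometryConfig(thickness_voxels=9)
    angles = np.linspace(-60.0, 60.0, 5)
    transforms = build_transforms(angles, geom, shape, det)
    return shape, det, geom, angles, transforms


@pytest.fixture
def thin_consistent_problem():
    """A single-z-layer system whose normalized operator is well conditioned.

    With nz=1 and a detector wide enough to catch every splat, the
    smallest singular value of the normalized operator is ~0.6, so a few
    hundred simultaneous iterations converge to the least-squares solution
    to machine precision — the regime where convergence contracts can be
    checked against a dense pseudo-inverse.
    """
    from tomoslab.formats_io import Volume
    from tomoslab.projector import forward_project

    shape = (1, 6, 8)
    det = (6, 12)
    geom = GeometryConfig(thickness_voxels=1)
    angles = np.linspace(-60.0, 60.0, 7)
    transforms = build_transforms(angles, geom, shape, det)
    x_true = np.random.default_rng(7).random(shape)
    ts = forward_project(Volume(data=x_true), transforms, det)
    return shape, det, transforms, x_true, ts
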