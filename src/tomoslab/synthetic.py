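"""Ground-truth phantoms and simulated tilt series.

Every algorithm and test in this package runs on data generated here:
geometric phantoms voxelized deterministically (a voxel belongs to a body
iff its center is inside), projected over a limited angular range so the
simulated series carries a realistic missing wedge (the fixtures use
+/-60 degrees at 2-degree steps, the common dose-symmetric survey range),
with additive Gaussian noise from a seeded generator.  Real cryo-ET data
additionally carry CTF modulation, dose-dependent damage and alignment
errors, none of which are modeled; what passes here validates operator
and solver correctness, not robustness to those effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import TiltSeries, Volume
from .geometry import GeometryConfig, build_transforms
from .projector import forward_project

__all__ = [
    "Body",
    "PhantomSpec",
    "NoiseSpec",
    "make_phantom",
    "simulate_tilt_series",
    "standard_fixture",
    "fixture_names",
]


@dataclass(frozen=True)
class Body:
    """One solid in a phantom: sphere, ellipsoid or cuboid.

    ``center`` is in (z, y, x) voxel coordinates; ``radii`` is a scalar
    for a sphere, or per-axis (z, y, x) semi-axes / half-extents for an
    ellipsoid / cuboid.  Later bodies overwrite earlier ones.
    """

    kind: str
    center: tuple[float, float, float]
    radii: float | tuple[float, float, float]
    value: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "ellipsoid", "cuboid"):
            raise ValueError(f"unknown body kind {self.kind!r}")
        r = np.atleast_1d(np.asarray(self.radii, dtype=np.float64))
        if np.any(r <= 0):
            raise ValueError("radii/half-extents must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int]
    bodies: tuple[Body, ...] = ()
    background: float = 0.0


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise with a fixed seed."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def make_phantom(spec: PhantomSpec) -> Volume:
    """Voxelize a phantom deterministically (center-inclusion, no antialiasing)."""
    nz, ny, nx = spec.shape
    vol = np.full((nz, ny, nx), spec.background, dtype=np.float64)
    zz, yy, xx = np.meshgrid(
        np.arange(nz, dtype=np.float64),
        np.arange(ny, dtype=np.float64),
        np.arange(nx, dtype=np.float64),
        indexing="ij",
    )
    for body in spec.bodies:
        cz, cy, cx = body.center
        if body.kind == "sphere":
            r = float(np.atleast_1d(body.radii)[0])
            inside = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        elif body.kind == "ellipsoid":
            rz, ry, rx = np.asarray(body.radii, dtype=np.float64)
            inside = (
                ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
                <= 1.0
            )
        else:  # cuboid
            hz, hy, hx = np.asarray(body.radii, dtype=np.float64)
            inside = (
                (np.abs(zz - cz) <= hz)
                & (np.abs(yy - cy) <= hy)
                & (np.abs(xx - cx) <= hx)
            )
        vol[inside] = body.value
    return Volume(data=vol)


def simulate_tilt_series(
    vol: Volume,
    angles_deg,
    geom: GeometryConfig,
    noise: NoiseSpec = NoiseSpec(),
) -> TiltSeries:
    """Forward-project the volume, then add seeded Gaussian noise.

    ``sigma=0`` returns the exact projections; an identical seed gives
    bitwise-identical output.
    """
    nz, ny, nx = vol.data.shape
    transforms = build_transforms(angles_deg, geom, (nz, ny, nx), (ny, nx))
    ts = forward_project(vol, transforms, (ny, nx))
    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        noisy = ts.images + rng.normal(0.0, noise.sigma, size=ts.images.shape)
        ts = TiltSeries(
            images=noisy, angles_deg=ts.angles_deg, pixel_size_nm=ts.pixel_size_nm
        )
    return ts


def _spheres_phantom(n: int) -> PhantomSpec:
    c = (n - 1) / 2.0
    return PhantomSpec(
        shape=(n, n, n),
        bodies=(
            Body("sphere", (c, c, c), n * 0.19, value=1.0),
            Body("sphere", (c - n * 0.17, c + n * 0.2, c - n * 0.2), n * 0.09, value=0.6),
            Body("sphere", (c + n * 0.2, c - n * 0.22, c + n * 0.14), n * 0.07, value=1.4),
            Body("cuboid", (c + n * 0.16, c + n * 0.22, c + n * 0.25), (n * 0.05, n * 0.08, n * 0.05), value=0.8),
        ),
    )


# Canonical fixtures shared by the tests and the worked examples.  Angles
# span the +/-60 degree missing-wedge range at 2-degree steps (61 tilts);
# noise sigma is ~10% of the peak projection value of the phantom.
_FIXTURES: dict[str, dict] = {
    "spheres-61tilt-pm60": dict(size=32, sigma=1.2, seed=20260928),
    "spheres-61tilt-pm60-clean": dict(size=32, sigma=0.0, seed=0),
    "spheres-61tilt-pm60-large": dict(size=48, sigma=1.8, seed=20260928),
}


def fixture_names() -> tuple[str, ...]:
    return tuple(_FIXTURES)


def standard_fixture(name: str) -> tuple[Volume, TiltSeries, GeometryConfig]:
    """A canonical (phantom, noisy tilt series, geometry) triple by name.

    Raises ``KeyError`` listing the registry on an unknown name.
    """
    try:
        cfg = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    n = cfg["size"]
    vol = make_phantom(_spheres_phantom(n))
    geom = GeometryConfig(thickness_voxels=n)
    angles = np.arange(-60.0, 60.0 + 1e-9, 2.0)
    ts = simulate_tilt_series(
        vol, angles, geom, NoiseSpec(sigma=cfg["sigma"], seed=cfg["seed"])
    )
    return vol, ts, geom
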