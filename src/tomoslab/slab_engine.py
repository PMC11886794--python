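"""y-axis slab decomposition: plan, execute on a worker pool, merge.

At zero pitch the projection model maps voxel row y to detector row y
exactly, so the whole reconstruction block-decouples along y and slabs
reproduce the unsliced result bit for bit.  With nonzero pitch each slab
additionally loads a halo of detector rows (see
:func:`tomoslab.geometry.required_halo`); where the halo extends past the
detector edge the boundary rows are replicated, which is the void-filling
rule.  Slabs are pure functions of their inputs and may run in any order
on the pool; cores are disjoint and merged by direct row assignment, so
results are independent of the worker count and of scheduling.

ADMM is refused here: its TV regularizer couples neighboring y-rows, so
it relies on global consistency of the volume and must run whole-volume.
"""

from __future__ import annotations

import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np

from .formats_io import TiltSeries, Volume
from .geometry import GeometryConfig, ProjectionTransform, required_halo
from .reconstruct import ReconstructionParams, reconstruct

__all__ = ["SlabPlan", "SlabDecompositionError", "plan_slabs", "run_sliced"]

SLICEABLE_METHODS = ("BPT", "WBP", "FBP", "SIRT", "SART")


class SlabDecompositionError(ValueError):
    """The requested method cannot run per-slab."""


@dataclass(frozen=True)
class SlabPlan:
    """Half-open core row ranges partitioning [0, ny), plus halo and pool size."""

    cores: tuple[tuple[int, int], ...]
    halo: int
    worker_count: int

    def __post_init__(self) -> None:
        if self.worker_count < 1:
            raise ValueError("worker_count must be >= 1")
        if self.halo < 0:
            raise ValueError("halo must be >= 0")
        prev = 0
        for y0, y1 in self.cores:
            if y0 != prev or y1 <= y0:
                raise ValueError("cores must be ordered, disjoint and cover [0, ny)")
            prev = y1


def plan_slabs(ny: int, n_workers: int, geom: GeometryConfig) -> SlabPlan:
    """Split [0, ny) into near-equal cores (sizes differ by at most 1)."""
    if ny < 1:
        raise ValueError("ny must be >= 1")
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    if n_workers > ny:
        warnings.warn(f"n_workers={n_workers} > ny={ny}; reducing to {ny}", stacklevel=2)
        n_workers = ny
    base, rem = divmod(ny, n_workers)
    cores = []
    start = 0
    for i in range(n_workers):
        size = base + (1 if i < rem else 0)
        cores.append((start, start + size))
        start += size
    return SlabPlan(cores=tuple(cores), halo=required_halo(geom), worker_count=n_workers)


def _run_slab(
    ts: TiltSeries,
    transforms: list[ProjectionTransform],
    vol_shape: tuple[int, int, int],
    params: ReconstructionParams,
    core: tuple[int, int],
    halo: int,
) -> np.ndarray:
    nz, ny, nx = vol_shape
    y0, y1 = core
    # Detector rows the slab needs; rows past the edge replicate the
    # boundary row (the fill rule for pitch-induced voids).
    rows = np.clip(np.arange(y0 - halo, y1 + halo), 0, ts.det_shape[0] - 1)
    sub_images = ts.images[:, rows, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate-angle warning already raised upstream
        sub_ts = TiltSeries(
            images=sub_images,
            angles_deg=ts.angles_deg.copy(),
            pixel_size_nm=ts.pixel_size_nm,
        )
    sub_transforms = [
        t.shifted(vol_origin=(0, y0, 0), det_origin=(float(y0 - halo), 0.0))
        for t in transforms
    ]
    sub_vol = reconstruct(sub_ts, sub_transforms, (nz, y1 - y0, nx), params)
    return np.asarray(sub_vol.data)


def run_sliced(
    ts: TiltSeries,
    transforms: list[ProjectionTransform],
    vol_shape: tuple[int, int, int],
    params: ReconstructionParams,
    plan: SlabPlan,
) -> Volume:
    """Reconstruct slab by slab and stack the cores along y.

    For zero pitch the output is bitwise identical to the unsliced
    reconstruction for every sliceable method and any worker count.
    """
    if params.method not in SLICEABLE_METHODS:
        raise SlabDecompositionError(
            f"method {params.method!r} cannot be decomposed into y-slabs: "
            "its update relies on global consistency of the whole volume "
            "(run it unsliced)"
        )
    nz, ny, nx = vol_shape
    if plan.cores[-1][1] != ny:
        raise ValueError(f"plan covers [0, {plan.cores[-1][1]}) but volume has ny={ny}")
    out = np.empty((nz, ny, nx), dtype=np.float64)

    def work(core: tuple[int, int]) -> tuple[tuple[int, int], np.ndarray]:
        return core, _run_slab(ts, transforms, vol_shape, params, core, plan.halo)

    if plan.worker_count == 1 or len(plan.cores) == 1:
        results = [work(c) for c in plan.cores]
    else:
        with ThreadPoolExecutor(max_workers=plan.worker_count) as pool:
            results = list(pool.map(work, plan.cores))
    for (y0, y1), data in results:
        out[:, y0:y1, :] = data
    return Volume(data=out, voxel_size_nm=ts.pixel_size_nm)
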