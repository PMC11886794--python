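"""The six reconstruction algorithms: BPT, WBP, FBP, SIRT, SART, ADMM.

All iterative methods start from x = 0, are fully deterministic (no RNG
anywhere), and use the same splat-weight normalization: R is the inverse
per-detector-pixel sum of splat weights (row sums) and C the inverse
per-voxel sum (column sums), with zeros wherever the weights vanish.
This component-wise Cimmino-style weighting makes a consistent system's
exact solution a fixed point and keeps the data residual non-increasing
for relaxation factors in (0, 1].

SIRT update:   x <- x + relax * C A^T R (b - A x)
SART update:   the same correction restricted to one tilt angle per
               sub-step, sweeping all angles once per iteration
ADMM:          min_x 1/2 ||Ax - b||^2 + lambda ||Dx||_1 with D the
               forward finite-difference operator along x, y and z
               (anisotropic total variation), split as Dx = z with
               penalty rho; the x-update takes a fixed small number of
               SIRT-normalized gradient steps on the augmented objective,
               the z-update is the elementwise soft-threshold with
               kappa = lambda / rho, followed by dual ascent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .formats_io import TiltSeries, Volume
from .geometry import ProjectionTransform
from .projector import FilterSpec, ProjectionOperator, apply_filter

__all__ = [
    "ReconstructionParams",
    "ConvergenceTrace",
    "DivergenceError",
    "METHODS",
    "ITERATIVE_METHODS",
    "bpt",
    "fbp",
    "wbp",
    "sirt",
    "sart",
    "admm",
    "soft_threshold",
    "grad3",
    "div3",
    "reconstruct",
]

METHODS = ("BPT", "WBP", "FBP", "SIRT", "SART", "ADMM")
ITERATIVE_METHODS = ("SIRT", "SART", "ADMM")


class DivergenceError(ArithmeticError):
    """An iterative method produced non-finite values."""


@dataclass(frozen=True)
class ReconstructionParams:
    """Algorithm selection plus the knobs the algorithms expose.

    ``n_iters``/``relax`` apply to SIRT/SART/ADMM; ``filter`` to FBP/WBP;
    ``admm_rho`` (penalty) and ``admm_lambda`` (TV weight) to ADMM.
    ``sart_order`` chooses the sweep order: ``ascending-angle`` (default,
    deterministic in the angle values) or ``file-order``.
    """

    method: str = "WBP"
    n_iters: int = 30
    relax: float = 1.0
    filter: FilterSpec = field(default_factory=lambda: FilterSpec(kind="exact-weighting"))
    admm_rho: float = 1.0
    admm_lambda: float = 0.1
    admm_inner_steps: int = 3
    sart_order: str = "ascending-angle"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.method in ITERATIVE_METHODS and self.n_iters < 1:
            raise ValueError("n_iters must be >= 1 for iterative methods")
        if not self.relax > 0:
            raise ValueError("relax must be > 0")
        if not self.admm_rho > 0:
            raise ValueError("admm_rho must be > 0")
        if self.admm_lambda < 0:
            raise ValueError("admm_lambda must be >= 0")
        if self.admm_inner_steps < 1:
            raise ValueError("admm_inner_steps must be >= 1")
        if self.sart_order not in ("file-order", "ascending-angle"):
            raise ValueError("sart_order must be 'file-order' or 'ascending-angle'")


@dataclass
class ConvergenceTrace:
    """Per-iteration diagnostics of an iterative reconstruction."""

    residual: list[float] = field(default_factory=list)  # ||Ax - b||_2
    primal: list[float] = field(default_factory=list)    # ADMM ||Dx - z||_2
    dual: list[float] = field(default_factory=list)      # ADMM rho*||D^T(z - z_prev)||_2


def _check_finite(x: np.ndarray, iteration: int) -> None:
    # guard both the iterate and its magnitude: the norm overflows to inf
    # a few iterations before individual voxels do
    with np.errstate(over="ignore"):
        ok = np.all(np.isfinite(x)) and np.isfinite(x.ravel().dot(x.ravel()))
    if not ok:
        raise DivergenceError(f"non-finite values at iteration {iteration}")


def _safe_inverse(w: np.ndarray) -> np.ndarray:
    out = np.zeros_like(w)
    nz = w > 0
    out[nz] = 1.0 / w[nz]
    return out


def _operator(ts: TiltSeries, transforms, vol_shape) -> ProjectionOperator:
    if len(transforms) != ts.n_tilts:
        raise ValueError("one transform per tilt image required")
    return ProjectionOperator(transforms, tuple(vol_shape), ts.det_shape)


def bpt(
    ts: TiltSeries,
    transforms: list[ProjectionTransform],
    vol_shape: tuple[int, int, int],
) -> Volume:
    """Normalized backprojection: adjoint divided by per-voxel hit weight.

    Uniform projection data reconstruct to uniform values inside the
    covered region; voxels never hit by any splat stay 0 and are recorded
    in the returned volume's ``coverage`` mask.
    """
    op = _operator(ts, transforms, vol_shape)
    acc = op.adjoint(ts.images)
    wsum = op.col_weight_sums()
    vol = acc * _safe_inverse(wsum)
    return Volume(data=vol, voxel_size_nm=ts.pixel_size_nm, coverage=wsum > 0)


def fbp(
    ts: TiltSeries,
    transforms: list[ProjectionTransform],
    vol_shape: tuple[int, int, int],
    filter: FilterSpec | None = None,
) -> Volume:
    """Filtered backprojection: ramp-filter the rows, then normalized BPT.

    The result is scaled by pi / (2 * n_tilts), the usual discretization
    of the inverse Radon angular integral.
    """
    spec = filter if filter is not None else FilterSpec(kind="ramp")
    if spec.kind not in ("ramp", "ramp-hamming", "ramp-hann"):
        raise ValueError(
            f"FBP needs a ramp-family filter, got {spec.kind!r} "
            "(use BPT for unfiltered, WBP for exact-weighting)"
        )
    return _filtered_backprojection(ts, transforms, vol_shape, spec)


def wbp(
    ts: TiltSeries,
    transforms: list[ProjectionTransform],
    vol_shape: tuple[int, int, int],
    filter: FilterSpec | None = None,
) -> Volume:
    """Weighted backprojection: FBP with the exact-weighting roll-off filter."""
    spec = filter if filter is not None else FilterSpec(kind="exact-weighting")
    if spec.kind != "exact-weighting":
        raise ValueError(f"WBP needs filter kind 'exact-weighting', got {spec.kind!r}")
    return _filtered_backprojection(ts, transforms, vol_shape, spec)


def _filtered_backprojection(ts, transforms, vol_shape, spec: FilterSpec) -> Volume:
    filtered = apply_filter(ts, spec)
    vol = bpt(filtered, transforms, vol_shape)
    scale = math.pi / (2.0 * ts.n_tilts)
    return Volume(
        data=vol.data * scale,
        voxel_size_nm=vol.voxel_size_nm,
        coverage=vol.coverage,
    )


def sirt(
    ts: TiltSeries,
    transforms: list[ProjectionTransform],
    vol_shape: tuple[int, int, int],
    params: ReconstructionParams,
    x0: np.ndarray | None = None,
) -> tuple[Volume, ConvergenceTrace]:
    """Simultaneous iterative reconstruction with Cimmino-style weighting."""
    op = _operator(ts, transforms, vol_shape)
    b = ts.images.astype(np.float64)
    r_inv = _safe_inverse(op.row_weight_sums())
    c_inv = _safe_inverse(op.col_weight_sums())
    x = np.zeros(op.vol_shape) if x0 is None else np.array(x0, dtype=np.float64)
    trace = ConvergenceTrace()
    for it in range(params.n_iters):
        resid = b - op.forward(x)
        x = x + params.relax * c_inv * op.adjoint(r_inv * resid)
        _check_finite(x, it)
        trace.residual.append(float(np.linalg.norm(b - op.forward(x))))
    return Volume(data=x, voxel_size_nm=ts.pixel_size_nm), trace


def sart(
    ts: TiltSeries,
    transforms: list[ProjectionTransform],
    vol_shape: tuple[int, int, int],
    params: ReconstructionParams,
    x0: np.ndarray | None = None,
) -> tuple[Volume, ConvergenceTrace]:
    """Algebraic reconstruction sweeping one tilt angle per sub-step.

    One iteration applies the SIRT-style normalized correction restricted
    to each projection in turn; with a single angle it coincides exactly
    with one SIRT iteration.
    """
    op = _operator(ts, transforms, vol_shape)
    b = ts.images.astype(np.float64)
    if params.sart_order == "ascending-angle":
        order = list(np.argsort(np.asarray([t.angle_deg for t in transforms]), kind="stable"))
    else:
        order = list(range(op.n_angles))
    r_inv_all = _safe_inverse(op.row_weight_sums())
    c_inv_per_angle = [_safe_inverse(op.col_weight_sums_one(i)) for i in range(op.n_angles)]
    x = np.zeros(op.vol_shape) if x0 is None else np.array(x0, dtype=np.float64)
    trace = ConvergenceTrace()
    for it in range(params.n_iters):
        for i in order:
            resid_i = b[i] - op.forward_one(x, i)
            x = x + params.relax * c_inv_per_angle[i] * op.adjoint_one(r_inv_all[i] * resid_i, i)
        _check_finite(x, it)
        trace.residual.append(float(np.linalg.norm(b - op.forward(x))))
    return Volume(data=x, voxel_size_nm=ts.pixel_size_nm), trace


def soft_threshold(v, kappa: float):
    """Elementwise soft threshold sign(v) * max(|v| - kappa, 0)."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    v = np.asarray(v, dtype=np.float64)
    out = np.sign(v) * np.maximum(np.abs(v) - kappa, 0.0)
    return float(out) if out.ndim == 0 else out


def grad3(x: np.ndarray) -> np.ndarray:
    """Forward finite differences along z, y, x with Neumann boundaries.

    Returns shape (3, nz, ny, nx); component k holds the difference along
    axis k, zero on the last plane of that axis.
    """
    g = np.zeros((3,) + x.shape, dtype=np.float64)
    g[0, :-1, :, :] = x[1:, :, :] - x[:-1, :, :]
    g[1, :, :-1, :] = x[:, 1:, :] - x[:, :-1, :]
    g[2, :, :, :-1] = x[:, :, 1:] - x[:, :, :-1]
    return g


def div3(g: np.ndarray) -> np.ndarray:
    """Discrete divergence, the negative adjoint of :func:`grad3`.

    Satisfies <grad3(x), g> == <x, -div3(g)> for all x, g.
    """
    out = np.zeros(g.shape[1:], dtype=np.float64)
    out[:-1, :, :] += g[0, :-1, :, :]
    out[1:, :, :] -= g[0, :-1, :, :]
    out[:, :-1, :] += g[1, :, :-1, :]
    out[:, 1:, :] -= g[1, :, :-1, :]
    out[:, :, :-1] += g[2, :, :, :-1]
    out[:, :, 1:] -= g[2, :, :, :-1]
    return out


def admm(
    ts: TiltSeries,
    transforms: list[ProjectionTransform],
    vol_shape: tuple[int, int, int],
    params: ReconstructionParams,
    x0: np.ndarray | None = None,
) -> tuple[Volume, ConvergenceTrace]:
    """TV-regularized least squares by ADMM, always on the whole volume.

    Solves min_x 1/2 ||Ax-b||^2 + lambda ||Dx||_1.  The TV term couples
    neighboring voxels in every direction, so this operation relies on
    global consistency of the volume and must never run per-slab (the
    slab engine enforces that).
    """
    op = _operator(ts, transforms, vol_shape)
    b = ts.images.astype(np.float64)
    r_inv = _safe_inverse(op.row_weight_sums())
    rho, lam = params.admm_rho, params.admm_lambda
    # Precondition the inner gradient steps with the diagonal bound of the
    # augmented Hessian A^T R A + rho D^T D: splat column weights plus the
    # Gershgorin row-sum bound of D^T D (4 per axis of extent > 1).  Same
    # normalization as SIRT on the fidelity part, and it keeps the steps
    # contractive for relax <= 1 regardless of rho.
    d_bound = 4.0 * sum(1 for s in vol_shape if s > 1)
    m_inv = 1.0 / (op.col_weight_sums() + rho * d_bound)
    x = np.zeros(op.vol_shape) if x0 is None else np.array(x0, dtype=np.float64)
    z = grad3(x)
    u = np.zeros_like(z)
    trace = ConvergenceTrace()
    for it in range(params.n_iters):
        for _ in range(params.admm_inner_steps):
            grad_fid = op.adjoint(r_inv * (op.forward(x) - b))
            grad_pen = -div3(grad3(x) - z + u) * rho
            x = x - params.relax * m_inv * (grad_fid + grad_pen)
        _check_finite(x, it)
        gx = grad3(x)
        z_prev = z
        z = soft_threshold(gx + u, lam / rho)
        u = u + gx - z
        trace.residual.append(float(np.linalg.norm(b - op.forward(x))))
        trace.primal.append(float(np.linalg.norm(gx - z)))
        trace.dual.append(float(rho * np.linalg.norm(div3(z - z_prev))))
    return Volume(data=x, voxel_size_nm=ts.pixel_size_nm), trace


def reconstruct(
    ts: TiltSeries,
    transforms: list[ProjectionTransform],
    vol_shape: tuple[int, int, int],
    params: ReconstructionParams,
) -> Volume:
    """Dispatch on ``params.method``; iterative traces are discarded here."""
    if params.method == "BPT":
        return bpt(ts, transforms, vol_shape)
    if params.method == "FBP":
        spec = params.filter
        if spec.kind == "exact-weighting":
            spec = replace(spec, kind="ramp")
        return fbp(ts, transforms, vol_shape, spec)
    if params.method == "WBP":
        spec = params.filter
        if spec.kind != "exact-weighting":
            spec = replace(spec, kind="exact-weighting")
        return wbp(ts, transforms, vol_shape, spec)
    if params.method == "SIRT":
        return sirt(ts, transforms, vol_shape, params)[0]
    if params.method == "SART":
        return sart(ts, transforms, vol_shape, params)[0]
    if params.method == "ADMM":
        return admm(ts, transforms, vol_shape, params)[0]
    raise ValueError(f"unknown method {params.method!r}")
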