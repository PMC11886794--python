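"""Reconstruction algorithms against dense oracles and convex references."""

import numpy as np
import pytest
import scipy.optimize

from tomoslab.formats_io import TiltSeries, Volume
from tomoslab.geometry import GeometryConfig, build_transforms
from tomoslab.projector import FilterSpec, forward_project
from tomoslab.reconstruct import (
    DivergenceError,
    ReconstructionParams,
    admm,
    bpt,
    div3,
    fbp,
    grad3,
    sart,
    sirt,
    soft_threshold,
    wbp,
)
from tomoslab.synthetic import Body, PhantomSpec, make_phantom, simulate_tilt_series

from conftest import dense_projection_matrix, weighted_pinv_solution


def _consistent_series(shape, det, transforms, rng):
    x = rng.random(shape)
    ts = forward_project(Volume(data=x), transforms, det)
    return x, ts


class TestBPT:
    def test_zero_series(self, tiny_geometry):
        shape, det, _, angles, transforms = tiny_geometry
        ts = TiltSeries(images=np.zeros((len(angles),) + det), angles_deg=angles)
        assert not np.any(bpt(ts, transforms, shape).data)

    def test_uniform_normalization(self):
        geom = GeometryConfig(thickness_voxels=6)
        transforms = build_transforms([0.0], geom, (6, 6, 6), (6, 6))
        ts = TiltSeries(images=np.ones((1, 6, 6)), angles_deg=[0.0])
        vol = bpt(ts, transforms, (6, 6, 6))
        np.testing.assert_allclose(vol.data[vol.coverage], 1.0, rtol=1e-12)

    def test_matches_dense_oracle(self, rng):
        shape, det = (12, 12, 12), (12, 12)
        geom = GeometryConfig(thickness_voxels=12)
        transforms = build_transforms(np.linspace(-50, 50, 5), geom, shape, det)
        ts = TiltSeries(images=rng.random((5,) + det), angles_deg=np.linspace(-50, 50, 5))
        a = dense_projection_matrix(transforms, shape, det)
        wsum = a.sum(axis=0)
        expected = np.where(wsum > 0, (a.T @ ts.images.astype(np.float64).ravel()) /
                            np.where(wsum > 0, wsum, 1.0), 0.0)
        got = bpt(ts, transforms, shape).data.ravel()
        np.testing.assert_allclose(got, expected, rtol=1e-6, atol=1e-12)


class TestFilteredMethods:
    def test_fbp_rejects_none_filter(self, tiny_geometry):
        shape, det, _, angles, transforms = tiny_geometry
        ts = TiltSeries(images=np.zeros((len(angles),) + det), angles_deg=angles)
        with pytest.raises(ValueError, match="ramp-family"):
            fbp(ts, transforms, shape, FilterSpec(kind="none"))
        with pytest.raises(ValueError, match="ramp-family"):
            fbp(ts, transforms, shape, FilterSpec(kind="exact-weighting"))

    def test_wbp_requires_exact_weighting(self, tiny_geometry):
        shape, det, _, angles, transforms = tiny_geometry
        ts = TiltSeries(images=np.zeros((len(angles),) + det), angles_deg=angles)
        with pytest.raises(ValueError, match="exact-weighting"):
            wbp(ts, transforms, shape, FilterSpec(kind="ramp"))

    @pytest.mark.parametrize("method,spec", [
        (fbp, FilterSpec(kind="ramp")),
        (wbp, FilterSpec(kind="exact-weighting")),
    ])
    def test_linearity(self, tiny_geometry, rng, method, spec):
        shape, det, _, angles, transforms = tiny_geometry
        imgs = rng.random((len(angles),) + det)
        v1 = method(TiltSeries(images=imgs, angles_deg=angles), transforms, shape, spec)
        v3 = method(TiltSeries(images=3 * imgs, angles_deg=angles), transforms, shape, spec)
        np.testing.assert_allclose(v3.data, 3 * v1.data, rtol=1e-5, atol=1e-7)

    def test_dense_angle_sphere_recovery(self):
        """Classical consistency: near-complete angular sampling recovers a sphere."""
        n = 24
        c = (n - 1) / 2
        vol = make_phantom(PhantomSpec((n, n, n), (Body("sphere", (c, c, c), 5.0),)))
        geom = GeometryConfig(thickness_voxels=n)
        angles = np.arange(-89.0, 90.0, 2.0)
        ts = simulate_tilt_series(vol, angles, geom)
        transforms = build_transforms(angles, geom, (n, n, n), (n, n))
        rec = fbp(ts, transforms, (n, n, n), FilterSpec(kind="ramp"))
        corr = np.corrcoef(rec.data.ravel(), vol.data.ravel())[0, 1]
        assert corr > 0.95


class TestSIRT:
    def test_exact_solution_is_fixed_point(self, thin_consistent_problem):
        shape, det, transforms, x_true, ts = thin_consistent_problem
        params = ReconstructionParams(method="SIRT", n_iters=5)
        out, trace = sirt(ts, transforms, shape, params, x0=x_true)
        # float32 storage of b makes the residual tiny but not exactly 0
        assert trace.residual[-1] < 1e-5
        np.testing.assert_allclose(out.data, x_true, atol=1e-5)

    def test_converges_to_weighted_pinv_solution(self, thin_consistent_problem):
        shape, det, transforms, x_true, ts = thin_consistent_problem
        params = ReconstructionParams(method="SIRT", n_iters=200, relax=1.0)
        out, trace = sirt(ts, transforms, shape, params)
        a = dense_projection_matrix(transforms, shape, det)
        b = ts.images.astype(np.float64).ravel()
        x_or = weighted_pinv_solution(a, b, a.sum(axis=1), a.sum(axis=0))
        rel = np.linalg.norm(out.data.ravel() - x_or) / np.linalg.norm(x_or)
        assert rel < 1e-3
        assert trace.residual[-1] / np.linalg.norm(b) < 1e-3

    def test_residual_monotone_on_noisy_phantom(self):
        vol, ts, geom = _noisy_fixture()
        transforms = build_transforms(ts.angles_deg, geom, vol.data.shape, ts.det_shape)
        params = ReconstructionParams(method="SIRT", n_iters=30, relax=1.0)
        _, trace = sirt(ts, transforms, vol.data.shape, params)
        assert all(a >= b - 1e-9 for a, b in zip(trace.residual, trace.residual[1:]))

    def test_divergence_guard(self, thin_consistent_problem):
        shape, det, transforms, x_true, ts = thin_consistent_problem
        params = ReconstructionParams(method="SIRT", n_iters=60, relax=500.0)
        with pytest.raises(DivergenceError, match="iteration"):
            sirt(ts, transforms, shape, params)


def _noisy_fixture():
    n = 16
    c = (n - 1) / 2
    vol = make_phantom(PhantomSpec((n, n, n), (Body("sphere", (c, c, c), 4.0),)))
    geom = GeometryConfig(thickness_voxels=n)
    angles = np.linspace(-60, 60, 9)
    from tomoslab.synthetic import NoiseSpec

    ts = simulate_tilt_series(vol, angles, geom, NoiseSpec(sigma=0.5, seed=11))
    return vol, ts, geom


class TestSART:
    def test_single_angle_equals_sirt(self, rng):
        shape, det = (6, 6, 6), (6, 10)
        geom = GeometryConfig(thickness_voxels=6)
        transforms = build_transforms([17.0], geom, shape, det)
        ts = TiltSeries(images=rng.random((1,) + det), angles_deg=[17.0])
        p1 = ReconstructionParams(method="SIRT", n_iters=1)
        p2 = ReconstructionParams(method="SART", n_iters=1)
        v_sirt, _ = sirt(ts, transforms, shape, p1)
        v_sart, _ = sart(ts, transforms, shape, p2)
        np.testing.assert_array_equal(v_sirt.data, v_sart.data)

    def test_residual_decreases_with_sweeps(self, tiny_geometry, rng):
        shape, det, _, angles, transforms = tiny_geometry
        x, ts = _consistent_series(shape, det, transforms, rng)
        _, t1 = sart(ts, transforms, shape, ReconstructionParams(method="SART", n_iters=1))
        _, t10 = sart(ts, transforms, shape, ReconstructionParams(method="SART", n_iters=10))
        assert t10.residual[-1] < t1.residual[-1]

    def test_same_fixed_point_as_sirt(self, thin_consistent_problem):
        shape, det, transforms, x_true, ts = thin_consistent_problem
        v_sirt, _ = sirt(ts, transforms, shape,
                         ReconstructionParams(method="SIRT", n_iters=200))
        v_sart, _ = sart(ts, transforms, shape,
                         ReconstructionParams(method="SART", n_iters=50))
        rel = np.linalg.norm(v_sart.data - v_sirt.data) / np.linalg.norm(v_sirt.data)
        assert rel < 1e-2

    def test_order_invariant_fixed_point(self, thin_consistent_problem):
        shape, det, transforms, x_true, ts = thin_consistent_problem
        va, _ = sart(ts, transforms, shape,
                     ReconstructionParams(method="SART", n_iters=60,
                                          sart_order="ascending-angle"))
        vf, _ = sart(ts, transforms, shape,
                     ReconstructionParams(method="SART", n_iters=60,
                                          sart_order="file-order"))
        np.testing.assert_allclose(va.data, vf.data, atol=1e-6)


class TestSoftThreshold:
    @pytest.mark.parametrize("v,kappa,expected", [
        (3.0, 1.0, 2.0),
        (0.5, 1.0, 0.0),
        (-3.0, 1.0, -2.0),
        (0.0, 0.0, 0.0),
        (-0.2, 0.0, -0.2),
    ])
    def test_closed_form(self, v, kappa, expected):
        assert soft_threshold(v, kappa) == expected

    def test_elementwise_on_arrays(self):
        out = soft_threshold(np.array([3.0, -0.5, -2.0]), 1.0)
        np.testing.assert_array_equal(out, [2.0, 0.0, -1.0])

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


class TestFiniteDifferences:
    def test_grad_div_adjoint(self, rng):
        x = rng.standard_normal((4, 5, 6))
        g = rng.standard_normal((3, 4, 5, 6))
        assert np.sum(grad3(x) * g) == pytest.approx(np.sum(x * (-div3(g))), rel=1e-12)


def _tv_oracle(b, lam):
    """Convex reference for min 1/2||x-b||^2 + lam*||Dx||_1 via constrained QP.

    Split formulation: variables (x, t) with t_j >= |(Dx)_j|, solved by
    SLSQP; independent of the ADMM path.
    """
    n = len(b)

    def unpack(v):
        return v[:n], v[n:]

    def fun(v):
        x, t = unpack(v)
        return 0.5 * np.sum((x - b) ** 2) + lam * np.sum(t)

    cons = []
    for j in range(n - 1):
        cons.append({"type": "ineq",
                     "fun": (lambda v, j=j: unpack(v)[1][j] - (v[j + 1] - v[j]))})
        cons.append({"type": "ineq",
                     "fun": (lambda v, j=j: unpack(v)[1][j] + (v[j + 1] - v[j]))})
    v0 = np.concatenate([b, np.abs(np.diff(b)) + 0.1])
    res = scipy.optimize.minimize(fun, v0, method="SLSQP", constraints=cons,
                                  options={"maxiter": 500, "ftol": 1e-12})
    assert res.success
    return res.x[:n]


class TestADMM:
    def test_lambda_zero_matches_unregularized_solution(self, thin_consistent_problem):
        shape, det, transforms, x_true, ts = thin_consistent_problem
        v_ref, _ = sirt(ts, transforms, shape,
                        ReconstructionParams(method="SIRT", n_iters=300))
        v_admm, _ = admm(ts, transforms, shape,
                         ReconstructionParams(method="ADMM", n_iters=150,
                                              admm_lambda=0.0))
        rel = np.linalg.norm(v_admm.data - v_ref.data) / np.linalg.norm(v_ref.data)
        assert rel < 1e-2

    def test_1d_tv_matches_convex_oracle(self):
        """Identity forward operator at zero tilt reduces ADMM to TV denoising."""
        b = np.array([1.0, 3.0, 2.5, -1.0, 0.5])
        lam = 0.5
        shape, det = (1, 1, 5), (1, 5)
        geom = GeometryConfig(thickness_voxels=1)
        transforms = build_transforms([0.0], geom, shape, det)
        ts = TiltSeries(images=b.reshape(1, 1, 5), angles_deg=[0.0])
        out, _ = admm(ts, transforms, shape,
                      ReconstructionParams(method="ADMM", n_iters=400,
                                           admm_rho=1.0, admm_lambda=lam))
        expected = _tv_oracle(b, lam)
        np.testing.assert_allclose(out.data.ravel(), expected, atol=1e-3)

    def test_large_lambda_flattens_volume(self, thin_consistent_problem):
        shape, det, transforms, x_true, ts = thin_consistent_problem
        out, _ = admm(ts, transforms, shape,
                      ReconstructionParams(method="ADMM", n_iters=200,
                                           admm_lambda=500.0))
        tv = np.abs(grad3(out.data)).sum()
        out0, _ = admm(ts, transforms, shape,
                       ReconstructionParams(method="ADMM", n_iters=200,
                                            admm_lambda=0.0))
        tv0 = np.abs(grad3(out0.data)).sum()
        assert tv < 0.05 * tv0

    def test_deterministic(self, thin_consistent_problem):
        shape, det, transforms, x_true, ts = thin_consistent_problem
        p = ReconstructionParams(method="ADMM", n_iters=20, admm_lambda=0.3)
        a, _ = admm(ts, transforms, shape, p)
        b_, _ = admm(ts, transforms, shape, p)
        np.testing.assert_array_equal(a.data, b_.data)


class TestDenseOracleEquivalence:
    """Operator implementations vs dense-matrix references on one geometry."""

    @pytest.fixture()
    def problem(self):
        shape, det = (10, 10, 10), (10, 12)
        geom = GeometryConfig(thickness_voxels=10, zshift_voxels=0.5)
        angles = np.linspace(-55, 55, 5)
        transforms = build_transforms(angles, geom, shape, det)
        rng = np.random.default_rng(3)
        x = rng.random(shape)
        ts = forward_project(Volume(data=x), transforms, det)
        a = dense_projection_matrix(transforms, shape, det)
        return shape, det, transforms, ts, a

    def test_sirt_matches_dense_iteration(self, problem):
        shape, det, transforms, ts, a = problem
        b = ts.images.astype(np.float64).ravel()
        row_w = a.sum(axis=1)
        col_w = a.sum(axis=0)
        ri = np.divide(1.0, row_w, out=np.zeros_like(row_w), where=row_w > 0)
        ci = np.divide(1.0, col_w, out=np.zeros_like(col_w), where=col_w > 0)
        x = np.zeros(a.shape[1])
        for _ in range(10):
            x = x + ci * (a.T @ (ri * (b - a @ x)))
        out, _ = sirt(ts, transforms, shape,
                      ReconstructionParams(method="SIRT", n_iters=10))
        np.testing.assert_allclose(out.data.ravel(), x, rtol=1e-6, atol=1e-12)

    def test_sart_matches_dense_sweep(self, problem):
        shape, det, transforms, ts, a = problem
        n_det = det[0] * det[1]
        b = ts.images.astype(np.float64).ravel()
        x = np.zeros(a.shape[1])
        order = np.argsort([t.angle_deg for t in transforms], kind="stable")
        for _ in range(10):
            for i in order:
                blk = a[i * n_det:(i + 1) * n_det]
                row_w = blk.sum(axis=1)
                col_w = blk.sum(axis=0)
                ri = np.divide(1.0, row_w, out=np.zeros_like(row_w), where=row_w > 0)
                ci = np.divide(1.0, col_w, out=np.zeros_like(col_w), where=col_w > 0)
                bi = b[i * n_det:(i + 1) * n_det]
                x = x + ci * (blk.T @ (ri * (bi - blk @ x)))
        out, _ = sart(ts, transforms, shape,
                      ReconstructionParams(method="SART", n_iters=10))
        np.testing.assert_allclose(out.data.ravel(), x, rtol=1e-6, atol=1e-12)
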