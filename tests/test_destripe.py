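"""MAP destriping: objective contracts, solver correctness, recovery.

The solver is cross-checked against an independently implemented
Chambolle-projection TV denoiser on the reduction psi = delta with an
l2 prior, which turns stripe estimation into classical ROF denoising.
"""

import numpy as np
import pytest

from mitospim import destripe as ds
from mitospim import synthetic as syn
from mitospim.volume import ImageVolume

from conftest import NOISE_FREE, psnr, small_scene

VOX = (0.645, 0.645, 1.0)


def delta_psi() -> np.ndarray:
    k = np.zeros((3, 3))
    k[1, 1] = 1.0
    return k


# --------------------------------------------------------------------------
# Independent oracle: Chambolle's projection algorithm for ROF denoising
# min_u ||u - f||^2 / 2 + w TV(u), dual fixed-point iteration on p.


def chambolle_rof(f: np.ndarray, weight: float, n_iter: int = 3000,
                  tau: float = 0.245) -> np.ndarray:
    p = np.zeros((2,) + f.shape)

    def grad(u):
        g = np.zeros_like(p)
        g[0, :-1, :] = u[1:, :] - u[:-1, :]
        g[1, :, :-1] = u[:, 1:] - u[:, :-1]
        return g

    def div(q):
        d = np.zeros_like(f)
        d[:-1, :] += q[0, :-1, :]
        d[1:, :] -= q[0, :-1, :]
        d[:, :-1] += q[1, :, :-1]
        d[:, 1:] -= q[1, :, :-1]
        return d

    for _ in range(n_iter):
        g = grad(div(p) - f / weight)
        denom = 1.0 + tau * np.sqrt((g**2).sum(axis=0))
        p = (p + tau * g) / denom
    return f - weight * div(p)


# --------------------------------------------------------------------------


class TestObjective:
    def test_zero_lambda_reduces_to_tv(self):
        rng = np.random.default_rng(0)
        u0 = rng.random((16, 16))
        model = ds.StripeModel(psi=delta_psi())
        assert np.isclose(
            ds.objective(u0, np.zeros_like(u0), model), ds.total_variation(u0)
        )

    def test_flat_image_has_zero_energy(self):
        u0 = np.full((8, 8), 0.7)
        model = ds.StripeModel(psi=delta_psi())
        assert ds.objective(u0, np.zeros_like(u0), model) == 0.0

    def test_vertical_edge_tv_is_rows_times_step(self):
        h = 0.35
        u0 = np.zeros((8, 8))
        u0[:, 4:] = h
        assert np.isclose(ds.total_variation(u0), 8 * h)

    def test_shape_mismatch_rejected(self):
        model = ds.StripeModel(psi=delta_psi())
        with pytest.raises(ValueError, match="shape"):
            ds.objective(np.zeros((8, 8)), np.zeros((9, 8)), model)


class TestDefaultPsi:
    def test_unit_l2_norm(self):
        psi = ds.default_psi(30.0, 1.0, VOX)
        assert abs(np.linalg.norm(psi) - 1.0) < 1e-12
        assert all(s % 2 == 1 for s in psi.shape)

    def test_isotropic_limit_is_rotation_symmetric(self):
        psi = syn.stripe_kernel(2.0, 2.0, (1.0, 1.0, 1.0))
        np.testing.assert_allclose(psi, np.rot90(psi), atol=1e-12)

    def test_second_moment_ratio_matches_sigmas(self):
        sa, sc = 8.0, 2.0
        psi = ds.default_psi(sa, sc, (1.0, 1.0, 1.0))
        w = psi**2
        ys, xs = np.mgrid[: psi.shape[0], : psi.shape[1]]
        ys = ys - (psi.shape[0] - 1) / 2
        xs = xs - (psi.shape[1] - 1) / 2
        mx = (w * xs**2).sum() / w.sum()
        my = (w * ys**2).sum() / w.sum()
        assert np.isclose(mx / my, (sa / sc) ** 2, rtol=0.02)

    def test_degenerate_sigmas_rejected(self):
        with pytest.raises(ValueError):
            ds.default_psi(1.0, 1.0, VOX)
        with pytest.raises(ValueError):
            ds.default_psi(3.0, -1.0, VOX)


class TestOperator:
    def test_convolution_adjoint_dot_product(self):
        rng = np.random.default_rng(1)
        psi = ds.default_psi(6.0, 1.0, VOX)
        conv = ds._ConvOp(psi, (40, 56))
        x = rng.normal(size=(1, 40, 56))
        y = rng.normal(size=(1, 40, 56))
        lhs = float(np.sum(conv(x) * y))
        rhs = float(np.sum(x * conv.adj(y)))
        assert abs(lhs - rhs) < 1e-8 * max(abs(lhs), 1.0)

    def test_grad_div_adjoint(self):
        rng = np.random.default_rng(2)
        u = rng.normal(size=(1, 13, 17))
        p = rng.normal(size=(1, 2, 13, 17))
        lhs = float(np.sum(ds._grad(u) * p))
        rhs = float(-np.sum(u * ds._div(p)))
        assert abs(lhs - rhs) < 1e-10


class TestEstimateStripes:
    def test_stripe_free_input_yields_near_zero_estimate(self):
        spec = small_scene(seed=2)
        truth = syn.place_nuclei(spec)
        u0 = syn.render_volume(truth, spec, NOISE_FREE).data[32]
        psi = ds.default_psi(30.0, 1.0, VOX)
        res = ds.estimate_stripes(u0, ds.StripeModel(psi=psi))
        assert np.linalg.norm(res.noise) < 1e-2 * np.linalg.norm(u0)

    def test_recovery_beats_corrupted_by_5db(self):
        spec = small_scene(seed=2)
        truth = syn.place_nuclei(spec)
        u = syn.render_volume(truth, spec, NOISE_FREE).data[30:33]
        b, _ = syn.make_stripe_field(u.shape, syn.StripeSpec(), VOX, seed=3)
        psi = ds.default_psi(30.0, 1.0, VOX)
        res = ds.destripe_volume(u + b, ds.StripeModel(psi=psi))
        gain = psnr(res.clean, u) - psnr(u + b, u)
        assert gain >= 5.0
        corr = np.corrcoef(res.noise.ravel(), b.ravel())[0, 1]
        assert corr >= 0.8

    def test_delta_psi_l2_matches_rof_oracle(self):
        rng = np.random.default_rng(4)
        u0 = np.clip(
            np.kron(rng.random((4, 4)), np.ones((8, 8)))
            + 0.05 * rng.normal(size=(32, 32)),
            0, 1,
        )
        alpha = 4.0
        model = ds.StripeModel(
            psi=delta_psi(), alpha=alpha, prior="l2", max_iter=4000, tol=1e-10
        )
        res = ds.estimate_stripes(u0, model)
        # psi = delta, l2: min_lam TV(u0-lam) + alpha/2 ||lam||^2
        # substituting u = u0-lam gives ROF with weight 1/alpha
        u_oracle = chambolle_rof(u0, 1.0 / alpha)
        u_hat = res.clean
        rel = np.linalg.norm(u_hat - u_oracle) / np.linalg.norm(u_oracle)
        assert rel < 1e-3

    def test_objective_trace_non_increasing(self):
        rng = np.random.default_rng(5)
        u0 = rng.random((32, 32))
        psi = ds.default_psi(5.0, 1.0, VOX)
        res = ds.estimate_stripes(u0, ds.StripeModel(psi=psi, max_iter=120))
        assert np.all(np.diff(res.objective_trace) <= 1e-9)

    def test_nonfinite_input_rejected(self):
        psi = ds.default_psi(5.0, 1.0, VOX)
        u0 = np.zeros((16, 16))
        u0[3, 3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            ds.estimate_stripes(u0, ds.StripeModel(psi=psi))

    def test_large_alpha_fixed_point(self):
        rng = np.random.default_rng(6)
        u0 = rng.random((24, 24))
        psi = ds.default_psi(5.0, 1.0, VOX)
        res = ds.estimate_stripes(
            u0, ds.StripeModel(psi=psi, alpha=1e4, max_iter=100)
        )
        assert np.allclose(res.lambda_hat, 0.0)
        np.testing.assert_allclose(res.clean, u0)

    def test_l1_scale_covariance(self):
        # TV and the l1 prior are both 1-homogeneous: scaling the image
        # scales the decomposition at unchanged alpha
        rng = np.random.default_rng(7)
        u0 = rng.random((24, 24))
        psi = ds.default_psi(5.0, 1.0, VOX)
        model = ds.StripeModel(psi=psi, alpha=0.5, max_iter=600, tol=1e-9)
        r1 = ds.estimate_stripes(u0, model)
        r2 = ds.estimate_stripes(3.0 * u0, model)
        assert (
            np.linalg.norm(r2.noise - 3.0 * r1.noise)
            < 5e-3 * np.linalg.norm(3.0 * r1.noise) + 1e-8
        )


class TestDestripeVolume:
    def test_per_slice_equals_independent_slice_solves(self):
        rng = np.random.default_rng(8)
        vol = rng.random((2, 32, 32))
        psi = ds.default_psi(5.0, 1.0, VOX)
        model = ds.StripeModel(psi=psi, max_iter=60)
        res = ds.destripe_volume(vol, model)
        for z in range(2):
            single = ds.estimate_stripes(vol[z], model)
            np.testing.assert_array_equal(res.lambda_hat[z], single.lambda_hat)
            assert res.objective_trace[z] == single.objective_trace

    def test_decomposition_identity(self):
        rng = np.random.default_rng(9)
        vol = ImageVolume(rng.random((3, 32, 32)), VOX)
        psi = ds.default_psi(5.0, 1.0, VOX)
        res = ds.destripe_volume(vol, ds.StripeModel(psi=psi, max_iter=40))
        recon = res.clean.data + res.noise.data
        rel = np.abs(recon - vol.data).max() / np.abs(vol.data).max()
        assert rel < 1e-6
        assert res.clean.voxel_size_um == vol.voxel_size_um

    def test_3d_solve_requires_3d_psi(self):
        psi = ds.default_psi(5.0, 1.0, VOX)
        model = ds.StripeModel(psi=psi, per_slice=False)
        with pytest.raises(ValueError, match="3D"):
            ds.destripe_volume(np.zeros((4, 16, 16)), model)
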