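"""Regularizers, analytic gradients and the Barzilai-Borwein solver."""

import hypothesis.extra.numpy as hnp
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, special

from cacstudy import fanbeam_sim, iq_metrics, recon_fbp, recon_ir
from cacstudy.fanbeam_sim import Sinogram, average_and_log, project, simulate_counts
from cacstudy.phantom_forge import GridSpec
from cacstudy.recon_ir import IrConfig, gamma_value, tv_value


def brute_force_tv(u, eps):
    """Literal per-pixel evaluation of the smoothed-TV discretization."""
    ny, nx = u.shape
    total = 0.0
    for i in range(ny):
        for j in range(nx):
            gy = u[i + 1, j] - u[i, j] if i + 1 < ny else 0.0
            gx = u[i, j + 1] - u[i, j] if j + 1 < nx else 0.0
            total += np.sqrt(gy**2 + gx**2 + eps)
    return total


class TestTvValue:
    def test_constant_image(self):
        u = np.full((5, 7), 3.0)
        assert tv_value(u, 1e-8) == pytest.approx(35 * 1e-4)

    def test_two_pixel_hand_value(self):
        u = np.array([[0.0], [1.0]])
        assert tv_value(u, 1e-8) == pytest.approx(brute_force_tv(u, 1e-8), rel=1e-12)

    def test_matches_brute_force_on_random_images(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            u = rng.normal(size=(5, 5))
            assert tv_value(u, 1e-8) == pytest.approx(brute_force_tv(u, 1e-8), rel=1e-12)

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(6, 6))
        assert tv_value(u + 17.0, 1e-8) == pytest.approx(tv_value(u, 1e-8), rel=1e-12)


class TestGammaValue:
    def test_constant_image_near_zero(self):
        u = np.full((4, 4), 2.0)
        assert gamma_value(u) == pytest.approx(0.0, abs=1e-3)

    def test_bounded_by_pixel_count(self):
        rng = np.random.default_rng(2)
        u = rng.normal(scale=100.0, size=(7, 9))
        assert gamma_value(u) <= 7 * 9

    def test_per_pixel_term_matches_quadrature(self):
        alpha, beta, g = 1.2, 0.6, 1.0
        quad, _ = integrate.quad(
            lambda x: x ** (alpha - 1) * beta**alpha * np.exp(-beta * x) / special.gamma(alpha),
            0.0,
            g,
        )
        assert special.gammainc(alpha, beta * g) == pytest.approx(quad, abs=1e-8)


@pytest.fixture(scope="module")
def tiny_problem():
    geom = fanbeam_sim.desk_geometry(n_channels=16, n_views=12)
    grid = GridSpec(nx=8, ny=8, nz=1, dx=12.0, dy=12.0)
    rng = np.random.default_rng(3)
    u = rng.normal(0, 0.01, (8, 8))
    f = rng.normal(0, 0.1, (12, 16))
    sino = Sinogram(f, geom, 1)
    return geom, grid, u, sino


class TestGradients:
    @pytest.mark.parametrize("reg", ["TV", "GAMMA"])
    def test_finite_difference_check(self, tiny_problem, reg):
        geom, grid, u, sino = tiny_problem
        cfg = IrConfig(regularizer=reg, lam=0.5)
        analytic = recon_ir.gradient(u, sino, geom, grid, cfg)
        fd = np.zeros_like(analytic)
        h = 1e-6
        for i in range(8):
            for j in range(8):
                up, um = u.copy(), u.copy()
                up[i, j] += h
                um[i, j] -= h
                fd[i, j] = (
                    recon_ir.objective(up, sino, geom, grid, cfg)
                    - recon_ir.objective(um, sino, geom, grid, cfg)
                ) / (2 * h)
        rel = np.abs(analytic - fd).max() / np.abs(fd).max()
        assert rel <= 1e-4

    def test_gradient_zero_at_exact_solution(self, tiny_problem):
        geom, grid, u, _ = tiny_problem
        ideal = project(u, geom, (grid.dy, grid.dx))
        sino = Sinogram(ideal, geom, 1)
        cfg = IrConfig(regularizer="TV", lam=0.0)
        g = recon_ir.gradient(u, sino, geom, grid, cfg)
        assert np.abs(g).max() < 1e-10

    def test_tv_gradient_zero_on_constant_image(self):
        g = recon_ir.tv_gradient(np.full((6, 6), 4.0), 1e-8)
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_objective_recomposition(self, tiny_problem):
        geom, grid, u, sino = tiny_problem
        for reg in ("TV", "GAMMA"):
            cfg = IrConfig(regularizer=reg, lam=2.5)
            whole = recon_ir.objective(u, sino, geom, grid, cfg)
            A = fanbeam_sim.system_matrix(geom, (8, 8), (grid.dy, grid.dx))
            r = A @ u.ravel() - sino.line_integrals.ravel()
            fid = float(r @ r)
            regval = float(recon_ir.regularizer_value(u, cfg))
            assert whole == pytest.approx(fid + 2.5 * regval, rel=1e-12)


class TestSolver:
    @pytest.mark.parametrize("reg", ["TV", "GAMMA"])
    def test_overall_descent(self, small_lnp_sinogram, small_geometry, small_grid, materials, reg):
        cfg = IrConfig(regularizer=reg, lam=0.05, n_iterations=60)
        _, trace = recon_ir.solve(small_lnp_sinogram, small_geometry, small_grid, materials, cfg)
        assert trace.objective[-1] <= trace.objective[0]
        assert len(trace.objective) == 60

    def test_convergence_trace_decays(self, small_lnp_sinogram, small_geometry, small_grid, materials):
        cfg = IrConfig(regularizer="TV", lam=0.05, n_iterations=500)
        _, trace = recon_ir.solve(small_lnp_sinogram, small_geometry, small_grid, materials, cfg)
        assert trace.delta_l2[-1] < 1e-3 * trace.delta_l2[9]

    def test_noise_monotone_weak_vs_strong(
        self, small_phantom, small_geometry, small_i0, materials
    ):
        """Stronger regularization denoises more on CNP-level (2-frame) data."""
        grid = small_phantom.grid
        ideal = project(small_phantom.mu[0], small_geometry, (grid.dy, grid.dx))
        sino = average_and_log(simulate_counts(ideal, small_i0, 2, seed=31), small_geometry)
        roi = small_phantom.background_mask()[0]
        for reg in ("TV", "GAMMA"):
            recs, _ = recon_ir.solve_batch(
                [sino] * 2, small_geometry, grid, materials, [0.02, 0.6],
                IrConfig(regularizer=reg, n_iterations=150),
            )
            weak = iq_metrics.noise_sd(recs[0].image, roi)
            strong = iq_metrics.noise_sd(recs[1].image, roi)
            assert strong < weak

    def test_unregularized_beats_fbp_on_noiseless_data(
        self, small_phantom, small_geometry, small_grid, materials
    ):
        grid = small_phantom.grid
        mu_true = small_phantom.mu[0]
        ideal = project(mu_true, small_geometry, (grid.dy, grid.dx))
        sino = Sinogram(ideal, small_geometry, 15)
        rec_fbp = recon_fbp.fbp(sino, recon_fbp.FbpKernel(), grid, materials, output="mu")
        cfg = IrConfig(regularizer="TV", lam=0.0, n_iterations=300)
        rec_ir, _ = recon_ir.solve(sino, small_geometry, grid, materials, cfg, output="mu")
        err_fbp = np.linalg.norm(rec_fbp.image - mu_true)
        err_ir = np.linalg.norm(rec_ir.image - mu_true)
        assert err_ir < err_fbp

    def test_deterministic(self, small_lnp_sinogram, small_geometry, small_grid, materials):
        cfg = IrConfig(regularizer="GAMMA", lam=0.1, n_iterations=30)
        a, _ = recon_ir.solve(small_lnp_sinogram, small_geometry, small_grid, materials, cfg)
        b, _ = recon_ir.solve(small_lnp_sinogram, small_geometry, small_grid, materials, cfg)
        np.testing.assert_array_equal(a.image, b.image)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            IrConfig(regularizer="L2")
        with pytest.raises(ValueError):
            IrConfig(lam=-1.0)
        with pytest.raises(ValueError):
            IrConfig(n_iterations=0)


class TestRegularizerProperties:
    """Property-based invariants of the regularization functionals."""

    images = hnp.arrays(
        dtype=float,
        shape=(6, 6),
        elements=st.floats(min_value=-1.0, max_value=1.0, allow_nan=False),
    )

    @given(u=images, c=st.floats(min_value=-10.0, max_value=10.0, allow_nan=False))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_shift_invariance(self, u, c):
        assert tv_value(u + c, 1e-8) == pytest.approx(tv_value(u, 1e-8), rel=1e-9)
        assert gamma_value(u + c) == pytest.approx(gamma_value(u), rel=1e-9, abs=1e-12)

    @given(u=images)
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_bounds(self, u):
        # smoothed TV is at least the per-pixel floor sqrt(eps); the gamma
        # penalty is a sum of CDF values in [0, 1]
        assert tv_value(u, 1e-8) >= 36 * 1e-4 - 1e-12
        assert 0.0 <= gamma_value(u) <= 36.0
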