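"""Forward model: chord accuracy, linearity, noise statistics, dose model."""

import numpy as np
import pytest

from cacstudy import fanbeam_sim, iq_metrics, recon_fbp
from cacstudy.phantom_forge import GridSpec
from cacstudy.fanbeam_sim import (
    FanBeamGeometry,
    Sinogram,
    average_and_log,
    desk_geometry,
    frames_per_degree,
    kerma_for_frames,
    project,
    simulate_counts,
)


@pytest.fixture(scope="module")
def disk_setup(small_grid):
    geom = desk_geometry(n_channels=96, n_views=90)
    x, y, _ = small_grid.axis_coords()
    xx, yy = np.meshgrid(x, y)
    r, mu0 = 40.0, 0.02
    disk = np.where(xx**2 + yy**2 <= r**2, mu0, 0.0)
    return geom, small_grid, disk, r, mu0


class TestGeometry:
    def test_source_to_isocenter(self):
        g = FanBeamGeometry()
        assert g.source_to_isocenter == pytest.approx(1953.0 - 133.8)

    def test_fan_must_cover_rod(self):
        with pytest.raises(ValueError, match="cover"):
            FanBeamGeometry(n_channels=16, detector_pitch=0.1)

    def test_view_angles_must_increase(self):
        with pytest.raises(ValueError):
            FanBeamGeometry(view_angles_deg=(0.0, 2.0, 1.0))


class TestProject:
    def test_chord_lengths_within_one_percent(self):
        # study-resolution grid; anti-aliased edge so the oracle probes the
        # projector rather than the disk rasterization
        from conftest import antialiased_disk

        geom = desk_geometry(n_channels=256, n_views=8)
        grid = GridSpec(nx=128, ny=128, nz=1, dx=0.75, dy=0.75)
        r, mu0 = 40.0, 0.02
        disk = antialiased_disk(grid, r, mu0)
        sino = project(disk, geom, (grid.dy, grid.dx))
        src, d = fanbeam_sim._ray_endpoints(geom, 0.0)
        tperp = np.abs(src[0] * d[:, 1] - src[1] * d[:, 0])
        inside = tperp < 0.95 * r
        chord = 2 * mu0 * np.sqrt(r**2 - tperp[inside] ** 2)
        err = np.abs(sino[0, inside] - chord) / chord
        assert err.max() <= 0.01

    def test_linearity(self, disk_setup):
        geom, grid, disk, _, _ = disk_setup
        rng = np.random.default_rng(0)
        other = rng.random(disk.shape) * 0.01
        lhs = project(2.0 * disk + 3.0 * other, geom, (grid.dy, grid.dx))
        rhs = 2.0 * project(disk, geom, (grid.dy, grid.dx)) + 3.0 * project(
            other, geom, (grid.dy, grid.dx)
        )
        np.testing.assert_allclose(lhs, rhs, rtol=1e-5, atol=1e-10)

    def test_zero_field_zero_projections(self, disk_setup):
        geom, grid, disk, _, _ = disk_setup
        sino = project(np.zeros_like(disk), geom, (grid.dy, grid.dx))
        assert np.all(sino == 0.0)

    def test_centered_disk_view_invariance(self, disk_setup):
        geom, grid, disk, _, _ = disk_setup
        sino = project(disk, geom, (grid.dy, grid.dx))
        per_view = sino.sum(axis=1)
        assert np.ptp(per_view) / per_view.mean() < 1e-3


class TestCounts:
    def test_unattenuated_mean(self):
        geom = desk_geometry(n_channels=96, n_views=4)
        ideal = np.zeros((4, 96))
        stack = simulate_counts(ideal, 1000.0, 15, seed=1)
        mean = stack.counts.mean()
        se = np.sqrt(1000.0 / stack.counts.size)
        assert abs(mean - 1000.0) < 3 * se

    def test_seed_determinism(self):
        ideal = np.random.default_rng(2).random((4, 8))
        a = simulate_counts(ideal, 500.0, 3, seed=7)
        b = simulate_counts(ideal, 500.0, 3, seed=7)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_poisson_variance_scaling(self):
        # summed counts over n frames: mean and variance both n i0 exp(-p)
        ideal = np.array([[0.0, 0.5, 1.0, 2.0]])
        i0, n = 200.0, 5
        sums = np.array(
            [simulate_counts(ideal, i0, n, seed=s).counts.sum(axis=0) for s in range(10_000)]
        )
        expected = n * i0 * np.exp(-ideal[0])
        var = sums.var(axis=0, ddof=1)
        # chi-square SE of a variance estimate: var x sqrt(2/(n-1))
        assert np.all(np.abs(var - expected) < 4 * expected * np.sqrt(2 / 9999))

    def test_frame_bounds(self):
        with pytest.raises(ValueError):
            simulate_counts(np.zeros((2, 2)), 100.0, 0, seed=0)
        with pytest.raises(ValueError):
            simulate_counts(np.zeros((2, 2)), 100.0, 16, seed=0)


class TestAverageAndLog:
    def test_inverts_exponential(self):
        geom = desk_geometry(n_channels=96, n_views=4)
        p = np.linspace(0, 3, 4 * 96).reshape(4, 96)
        i0 = 1e6
        counts = (i0 * np.exp(-p))[None, :, :].repeat(3, axis=0)
        stack = fanbeam_sim.CountFrameStack(counts=counts, i0_per_frame=i0, seed=0)
        sino = average_and_log(stack, geom)
        np.testing.assert_allclose(sino.line_integrals, p, rtol=1e-12)

    def test_zero_counts_guarded(self):
        geom = desk_geometry(n_channels=96, n_views=2)
        counts = np.zeros((1, 2, 96))
        stack = fanbeam_sim.CountFrameStack(counts=counts, i0_per_frame=100.0, seed=0)
        sino = average_and_log(stack, geom)
        assert np.all(np.isfinite(sino.line_integrals))

    def test_fifteen_frame_noise_reduction(self, disk_setup):
        geom, grid, disk, _, _ = disk_setup
        ideal = project(disk, geom, (grid.dy, grid.dx))
        i0 = 5000.0
        s1 = average_and_log(simulate_counts(ideal, i0, 1, seed=3), geom)
        s15 = average_and_log(simulate_counts(ideal, i0, 15, seed=3), geom)
        sd1 = (s1.line_integrals - ideal).std()
        sd15 = (s15.line_integrals - ideal).std()
        assert sd1 / sd15 == pytest.approx(np.sqrt(15), rel=0.10)


class TestDoseModel:
    @pytest.mark.parametrize("frames,kerma", [(1, 0.098), (2, 0.197), (15, 1.475)])
    def test_frame_proportional_kerma(self, frames, kerma):
        assert kerma_for_frames(frames) == kerma

    def test_invalid_frames_rejected(self):
        with pytest.raises(ValueError):
            kerma_for_frames(0)

    def test_sixty_hertz_at_four_degrees_per_second(self):
        assert frames_per_degree(60.0, 4.0) == 15


class TestCalibrateI0:
    """Quantum-noise calibration (SD of noisy-minus-noiseless FBP)."""

    @staticmethod
    def _quantum_sd(phantom, geometry, ideal, i0, frames, seed):
        grid = phantom.grid
        kernel = recon_fbp.FbpKernel()
        noiseless = recon_fbp.fbp(
            Sinogram(ideal, geometry, frames), kernel, grid, phantom.materials
        ).image
        sino = average_and_log(simulate_counts(ideal, i0, frames, seed=seed), geometry)
        rec = recon_fbp.fbp(sino, kernel, grid, phantom.materials)
        return iq_metrics.noise_sd(rec.image - noiseless, phantom.background_mask()[0])

    def test_self_consistent_noise(self, small_phantom, small_geometry, small_i0):
        grid = small_phantom.grid
        ideal = project(small_phantom.mu[0], small_geometry, (grid.dy, grid.dx))
        sd = self._quantum_sd(small_phantom, small_geometry, ideal, small_i0, 15, 99)
        assert 7.0 <= sd <= 7.8

    def test_one_frame_noise_scales_like_sqrt15(self, small_phantom, small_geometry, small_i0):
        grid = small_phantom.grid
        ideal = project(small_phantom.mu[0], small_geometry, (grid.dy, grid.dx))
        sds = {}
        for frames in (1, 15):
            vals = [
                self._quantum_sd(small_phantom, small_geometry, ideal, small_i0, frames, seed)
                for seed in (5, 6, 7)
            ]
            sds[frames] = np.mean(vals)
        assert sds[1] / sds[15] == pytest.approx(np.sqrt(15), rel=0.15)

    def test_noise_monotone_in_i0(self, small_phantom, small_geometry):
        grid = small_phantom.grid
        ideal = project(small_phantom.mu[0], small_geometry, (grid.dy, grid.dx))
        sds = [
            self._quantum_sd(small_phantom, small_geometry, ideal, i0, 15, 8)
            for i0 in (2e3, 2e4, 2e5)
        ]
        assert sds[0] > sds[1] > sds[2]
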