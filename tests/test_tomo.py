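"""Phase-space tomography: projection operators, RL updates, DAO."""

import numpy as np
import pytest
from scipy import sparse

from slfm import lfsim, realign, tomo
from slfm.lfsim import Volume3D, ZernikeWavefront
from slfm.realign import SpatialAngularViews
from slfm.tomo import (ReconstructionConfig, WavefrontMap, back_project,
                       estimate_dao, forward_project, reconstruct, rl_step)

from conftest import interior_beads, lateral_fwhm_um

NZ, NY, NX, A = 8, 32, 32, 5
VOXEL = (2 / 7, 0.25, 0.25)


@pytest.fixture(scope="module")
def psf_oracle():
    """Deeper 8-plane PSF for the system-matrix comparisons."""
    return lfsim.build_psf(na=1.0, wavelength_um=0.525, n_angles_side=A,
                           z_planes_um=np.linspace(-1.0, 1.0, NZ),
                           pixel_size_um=0.25, kernel_px=13)


def conv_matrix(kern: np.ndarray, ny: int, nx: int) -> sparse.csr_matrix:
    """Explicit zero-padded 2D convolution operator for one kernel."""
    k = kern.shape[0]
    half = k // 2
    ys, xs = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    rows, cols, vals = [], [], []
    for dy in range(-half, half + 1):
        for dx in range(-half, half + 1):
            w = kern[dy + half, dx + half]
            if w == 0:
                continue
            yi, xi = ys + dy, xs + dx
            ok = (yi >= 0) & (yi < ny) & (xi >= 0) & (xi < nx)
            rows.append(ys[ok] * nx + xs[ok])
            cols.append(yi[ok] * nx + xi[ok])
            vals.append(np.full(int(ok.sum()), w))
    return sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ny * nx, ny * nx))


@pytest.fixture(scope="module")
def system_matrix(psf_oracle):
    """The full measurement operator, one row block per angular view."""
    disk = psf_oracle.in_disk()
    blocks = []
    empty = sparse.csr_matrix((NY * NX, NY * NX))
    for iu in range(A):
        for iv in range(A):
            zb = [conv_matrix(psf_oracle.kernels[iu, iv, iz][::-1, ::-1],
                              NY, NX) if disk[iu, iv] else empty
                  for iz in range(NZ)]
            blocks.append(sparse.hstack(zb))
    return sparse.vstack(blocks).tocsr()


@pytest.fixture(scope="module")
def bead_volume():
    return interior_beads(3, NZ, NY, 8, seed=3, fwhm_um=0.4, voxel=VOXEL)


class TestForwardProject:
    def test_zero_volume_projects_to_zero(self, psf_oracle):
        vol = Volume3D(np.zeros((NZ, NY, NX)), VOXEL)
        assert forward_project(vol, psf_oracle).data.sum() == 0.0

    def test_linearity(self, psf_oracle):
        rng = np.random.default_rng(0)
        v1 = rng.random((NZ, NY, NX))
        v2 = rng.random((NZ, NY, NX))
        f = lambda v: forward_project(Volume3D(v, VOXEL), psf_oracle).data
        lhs = f(2.0 * v1 + 0.5 * v2)
        rhs = 2.0 * f(v1) + 0.5 * f(v2)
        assert np.abs(lhs - rhs).max() <= 1e-6 * np.abs(rhs).max()

    def test_point_source_appears_at_analytic_disparity(self, psf_oracle):
        vol = np.zeros((NZ, NY, NX))
        vol[1, NY // 2, NX // 2] = 1.0  # off-focus plane
        views = forward_project(Volume3D(vol, VOXEL), psf_oracle).data
        ty, tx = psf_oracle.angle_tangents()
        z = psf_oracle.z_planes_um[1]
        yy, xx = np.mgrid[:NY, :NX]
        for iu, iv in [(2, 4), (1, 2), (3, 3)]:
            v = views[iu, iv]
            cy = (yy * v).sum() / v.sum() - NY // 2
            cx = (xx * v).sum() / v.sum() - NX // 2
            assert cy == pytest.approx(z * ty[iu, iv] / 0.25, abs=0.2)
            assert cx == pytest.approx(z * tx[iu, iv] / 0.25, abs=0.2)

    def test_matches_system_matrix(self, psf_oracle, system_matrix):
        rng = np.random.default_rng(1)
        v = rng.random((NZ, NY, NX))
        mine = forward_project(Volume3D(v, VOXEL), psf_oracle).data
        oracle = (system_matrix @ v.ravel()).reshape(A, A, NY, NX)
        assert np.abs(mine - oracle).max() <= 1e-10 * oracle.max()

    def test_flux_conserved_for_interior_object(self, psf_oracle,
                                                bead_volume):
        views = forward_project(bead_volume, psf_oracle)
        assert views.data.sum() == pytest.approx(bead_volume.total_flux(),
                                                 rel=1e-3)


class TestAdjointness:
    def test_inner_products_agree(self, psf_oracle):
        rng = np.random.default_rng(2)
        v = rng.random((NZ, NY, NX))
        w = rng.standard_normal((A, A, NY, NX))
        fv = forward_project(Volume3D(v, VOXEL), psf_oracle).data
        bw = back_project(SpatialAngularViews(w, A, 3), psf_oracle)
        ip1 = float((fv * w).sum())
        ip2 = float((v * bw).sum())
        assert abs(ip1 - ip2) <= 1e-5 * abs(ip1)

    def test_adjointness_with_wavefront_shifts(self, psf_oracle):
        rng = np.random.default_rng(3)
        shifts = np.zeros((A, A, 2))
        disk = psf_oracle.in_disk()
        shifts[disk] = rng.uniform(-1.5, 1.5, (int(disk.sum()), 2))
        shifts[disk] -= shifts[disk].mean(axis=0)
        wf = WavefrontMap(shifts)
        v = rng.random((NZ, NY, NX))
        w = rng.standard_normal((A, A, NY, NX))
        fv = forward_project(Volume3D(v, VOXEL), psf_oracle, wf).data
        bw = back_project(SpatialAngularViews(w, A, 3), psf_oracle, wf)
        ip1 = float((fv * w).sum())
        ip2 = float((v * bw).sum())
        assert abs(ip1 - ip2) <= 1e-5 * abs(ip1)


class TestRichardsonLucy:
    def test_consistent_volume_is_fixed_point(self, psf_oracle, bead_volume):
        # strictly positive volume keeps forward >> epsilon everywhere,
        # so the update ratio is 1 up to the division guard
        vol = Volume3D(bead_volume.data + 0.05 * bead_volume.data.max(),
                       VOXEL)
        views = forward_project(vol, psf_oracle)
        stepped = rl_step(vol, views, psf_oracle)
        ratio = stepped.data / vol.data
        assert np.abs(ratio - 1.0).max() < 1e-6

    def test_nonnegativity_preserved(self, psf_oracle, bead_volume):
        views = forward_project(bead_volume, psf_oracle)
        vol = Volume3D(np.full((NZ, NY, NX), views.data.mean()), VOXEL)
        for _ in range(3):
            vol = rl_step(vol, views, psf_oracle)
            assert vol.data.min() >= 0.0

    def test_flux_conserved_per_iteration(self, psf_oracle, bead_volume):
        views = forward_project(bead_volume, psf_oracle)
        vol = Volume3D(np.full((NZ, NY, NX),
                               views.data.sum() / (NZ * NY * NX)), VOXEL)
        for _ in range(5):
            prev = vol.total_flux()
            vol = rl_step(vol, views, psf_oracle)
        assert vol.total_flux() == pytest.approx(bead_volume.total_flux(),
                                                 rel=1e-3)

    def test_matches_dense_oracle_over_20_iterations(self, psf_oracle,
                                                     system_matrix,
                                                     bead_volume):
        """The convolution-based RL iteration equals the explicit
        system-matrix iteration to 1e-5 relative."""
        views = forward_project(bead_volume, psf_oracle)
        eps = 1e-9
        init = views.data.sum() / (NZ * NY * NX)
        mine = Volume3D(np.full((NZ, NY, NX), init), VOXEL)
        ones = SpatialAngularViews(np.ones_like(views.data), A, 3)
        sens = back_project(ones, psf_oracle)
        y = views.data.ravel()
        x = np.full(NZ * NY * NX, init)
        sens_m = system_matrix.T @ np.ones_like(y)
        for _ in range(20):
            mine = rl_step(mine, views, psf_oracle, sensitivity=sens)
            x = x * (system_matrix.T @ (y / (system_matrix @ x + eps))) \
                / np.maximum(sens_m, eps)
        oracle = x.reshape(NZ, NY, NX)
        assert np.abs(mine.data - oracle).max() <= 1e-5 * oracle.max()

    def test_poisson_nll_non_increasing(self, psf_oracle, bead_volume):
        views = forward_project(bead_volume, psf_oracle)
        meas = views.data
        vol = Volume3D(np.full((NZ, NY, NX),
                               meas.sum() / (NZ * NY * NX)), VOXEL)

        def nll(v):
            pred = forward_project(v, psf_oracle).data + 1e-12
            return float((pred - meas * np.log(pred)).sum())

        values = [nll(vol)]
        for _ in range(10):
            vol = rl_step(vol, views, psf_oracle)
            values.append(nll(vol))
        assert all(b <= a + 1e-9 * abs(a)
                   for a, b in zip(values, values[1:]))

    def test_all_zero_measurement_rejected(self, psf_oracle, bead_volume):
        zero = SpatialAngularViews(np.zeros((A, A, NY, NX)), A, 3)
        with pytest.raises(ValueError):
            rl_step(bead_volume, zero, psf_oracle)


class TestReconstruct:
    def test_zero_iterations_returns_uniform_volume(self, psf_oracle,
                                                    bead_volume):
        views = forward_project(bead_volume, psf_oracle)
        vol, _ = reconstruct(views, psf_oracle,
                             ReconstructionConfig(n_iters=0))
        assert np.ptp(vol.data) == 0.0
        assert vol.total_flux() == pytest.approx(float(views.data.sum()))

    def test_bead_localized_within_one_voxel(self, psf_oracle):
        vol = interior_beads(1, NZ, NY, 8, seed=7, fwhm_um=0.4, voxel=VOXEL)
        true = np.unravel_index(np.argmax(vol.data), vol.data.shape)
        views = forward_project(vol, psf_oracle)
        rec, _ = reconstruct(views, psf_oracle,
                             ReconstructionConfig(n_iters=8))
        got = np.unravel_index(np.argmax(rec.data), rec.data.shape)
        assert all(abs(int(a) - int(b)) <= 1 for a, b in zip(true, got))


class TestDao:
    def test_unaberrated_views_give_null_map(self, psf_oracle):
        vol = interior_beads(6, NZ, NY, 10, seed=11, fwhm_um=0.4,
                             voxel=VOXEL)
        views = forward_project(vol, psf_oracle)
        est, _ = reconstruct(views, psf_oracle,
                             ReconstructionConfig(n_iters=16))
        wf = estimate_dao(views, est, psf_oracle)
        assert wf.max_shift() < 0.05

    def test_injected_shift_recovered_within_tenth_pixel(self, psf_oracle):
        vol = interior_beads(6, NZ, NY, 10, seed=11, fwhm_um=0.4,
                             voxel=VOXEL)
        disk = psf_oracle.in_disk()
        shifts = np.zeros((A, A, 2))
        shifts[2, 3] = (1.5, -0.7)
        views = forward_project(vol, psf_oracle, WavefrontMap(shifts.copy()))
        est, _ = reconstruct(views, psf_oracle,
                             ReconstructionConfig(n_iters=8))
        wf = estimate_dao(views, est, psf_oracle)
        expected = shifts.copy()
        expected[disk] -= shifts[disk].mean(axis=0)
        err = np.abs(wf.shifts[disk] - expected[disk]).max()
        assert err < 0.1

    def test_pure_tilt_gauge_fixed_to_zero(self, psf_oracle, bead_volume):
        # a global tilt translates every view identically
        disk = psf_oracle.in_disk()
        shifts = np.zeros((A, A, 2))
        shifts[disk] = (0.8, -1.1)
        views = forward_project(bead_volume, psf_oracle,
                                WavefrontMap(np.zeros((A, A, 2))))
        shifted = tomo._shift_views(views.data, WavefrontMap(shifts), +1.0)
        sviews = SpatialAngularViews(shifted, A, 3)
        est, _ = reconstruct(sviews, psf_oracle,
                             ReconstructionConfig(n_iters=6))
        wf = estimate_dao(sviews, est, psf_oracle)
        assert wf.max_shift() < 0.1

    def test_featureless_views_flagged_low_confidence(self, psf_oracle):
        flat = SpatialAngularViews(np.ones((A, A, NY, NX)), A, 3)
        vol = Volume3D(np.ones((NZ, NY, NX)), VOXEL)
        wf = estimate_dao(flat, vol, psf_oracle)
        assert wf.max_shift() == 0.0
        assert not wf.confident.any()


class TestAberratedReconstruction:
    def test_dao_restores_bead_width_under_astigmatism(self, psf_wide):
        """0.5-wavelength astigmatism: with DAO the bead FWHM returns to
        within 1.2x the unaberrated width; without DAO it stays larger."""
        vol = interior_beads(5, 5, 72, 20, seed=4)
        psf_ab = lfsim.apply_aberration(psf_wide, ZernikeWavefront({6: 0.5}))
        views_ab = forward_project(vol, psf_ab)
        views_cl = forward_project(vol, psf_wide)
        rec_clean, _ = reconstruct(views_cl, psf_wide,
                                   ReconstructionConfig(n_iters=8))
        rec_off, _ = reconstruct(views_ab, psf_wide,
                                 ReconstructionConfig(n_iters=8))
        rec_on, _ = reconstruct(views_ab, psf_wide,
                                ReconstructionConfig(n_iters=12, dao=True,
                                                     dao_start_iter=2,
                                                     dao_every=2))
        f_clean = lateral_fwhm_um(rec_clean)
        f_off = lateral_fwhm_um(rec_off)
        f_on = lateral_fwhm_um(rec_on)
        assert f_on <= 1.2 * f_clean
        assert f_off > f_on
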