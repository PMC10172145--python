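"""Shared fixtures: a small 5x5-angle optical model and phantoms.

The desk-scale geometry used throughout the suite: 5x5 angular views,
NA 1.0 (oil), 0.525 um emission, 5 z-planes over +/-1 um, fine-grid view
sampling of 0.25 um.  This keeps every stage exercisable in seconds while
preserving the disparity/blur structure of the full 13x13 instrument.
"""

from __future__ import annotations

import numpy as np
import pytest

from slfm import lfsim, metrics, realign, tomo


@pytest.fixture(scope="session")
def z_planes():
    return np.linspace(-1.0, 1.0, 5)


@pytest.fixture(scope="session")
def psf_small(z_planes):
    return lfsim.build_psf(na=1.0, wavelength_um=0.525, n_angles_side=5,
                           z_planes_um=z_planes, pixel_size_um=0.25,
                           kernel_px=13)


@pytest.fixture(scope="session")
def psf_wide(z_planes):
    """Same geometry with extra kernel headroom for aberration shifts."""
    return lfsim.build_psf(na=1.0, wavelength_um=0.525, n_angles_side=5,
                           z_planes_um=z_planes, pixel_size_um=0.25,
                           kernel_px=23)


def interior_beads(n_beads: int, nz: int, side: int, margin: int,
                   seed: int, fwhm_um: float = 0.3,
                   voxel=(0.5, 0.25, 0.25)) -> lfsim.Volume3D:
    """Beads kept `margin` pixels away from the lateral borders so that
    disparity and DAO shifts never push content off the field."""
    inner = lfsim.generate_beads(n_beads, (nz, side - 2 * margin,
                                           side - 2 * margin),
                                 bead_fwhm_um=fwhm_um, voxel_size_um=voxel,
                                 seed=seed)
    return lfsim.Volume3D(np.pad(inner.data, ((0, 0), (margin, margin),
                                              (margin, margin))),
                          inner.voxel_size_um)


@pytest.fixture(scope="session")
def bead_scene(psf_small):
    """One bead + its noiseless scan series on a 24-lens field."""
    vol = interior_beads(1, 5, 72, 20, seed=2)
    series = lfsim.render_scan_series(vol, psf_small)
    return vol, series


def lateral_fwhm_um(volume: lfsim.Volume3D, pixel_um: float = 0.25) -> float:
    """Mean x/y Gaussian-fit FWHM through the brightest voxel."""
    zz, yy, xx = np.unravel_index(np.argmax(volume.data), volume.data.shape)
    fx = metrics.fwhm_gaussian(volume.data[zz, yy, :], pixel_um)
    fy = metrics.fwhm_gaussian(volume.data[zz, :, xx], pixel_um)
    return 0.5 * (fx + fy)


def gain_fitted_snr_db(truth: np.ndarray, estimate: np.ndarray) -> float:
    """SNR after fitting a global gain (absolute camera gain is arbitrary)."""
    alpha = float((truth * estimate).sum() / (estimate * estimate).sum())
    return metrics.snr_db(metrics.MetricPair(truth, alpha * estimate))


def views_as_stack(views: realign.SpatialAngularViews) -> np.ndarray:
    a = views.n_angles_side
    return np.asarray(views.data, dtype=np.float64).reshape(
        a * a, *views.data.shape[2:])
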