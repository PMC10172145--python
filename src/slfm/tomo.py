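"""Iterative phase-space tomography with digital adaptive optics (DAO).

The forward model is linear: angular view (u, v) of a volume is the sum
over depth of 2D convolutions with the phase-space PSF kernels,

    view(u, v) = sum_z  volume[z] * kernel[u, v, z]          (+ optional
                                                              per-angle shift)

and the backprojector is its exact adjoint (correlation with the same
kernels).  Reconstruction runs multiplicative Richardson-Lucy updates,
the maximum-likelihood iteration for Poisson noise, jointly over all
angular views.  DAO estimates one lateral shift per angular view by
registering each measured view against its re-projection from the current
volume estimate; the shift map samples the pupil wavefront gradient, so
applying it during the remaining iterations corrects aberrations
computationally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .lfsim import PhaseSpacePSF, Volume3D, ZernikeWavefront, zernike_noll
from .realign import SpatialAngularViews

__all__ = [
    "WavefrontMap",
    "ReconstructionConfig",
    "forward_project",
    "back_project",
    "rl_step",
    "estimate_dao",
    "reconstruct",
]


@dataclass
class WavefrontMap:
    """Per-angle lateral shift estimates (view pixels) sampling the pupil
    wavefront gradient.

    ``shifts`` has shape (a, a, 2) as (dy, dx); the mean over in-pupil
    angles is zero (global translation gauge fixed).  ``zernike`` holds
    optional fitted mode coefficients, ``residual`` the fit RMS in pixels,
    ``confident`` flags angles whose correlation peak was usable.
    """

    shifts: np.ndarray
    zernike: dict[int, float] = field(default_factory=dict)
    residual: float = 0.0
    confident: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=np.float64)
        if self.shifts.ndim != 3 or self.shifts.shape[2] != 2:
            raise ValueError("shifts must have shape (a, a, 2)")

    def max_shift(self) -> float:
        return float(np.abs(self.shifts).max())


@dataclass
class ReconstructionConfig:
    """Settings for :func:`reconstruct`.

    Few Richardson-Lucy iterations suffice for phase-space deconvolution;
    the default schedule estimates DAO after iteration ``dao_start_iter``
    and refreshes it every ``dao_every`` iterations.
    """

    n_iters: int = 5
    dao: bool = False
    dao_start_iter: int = 2
    dao_every: int = 2
    zernike_max_order: int = 0      # 0 = raw shifts, no Zernike smoothing
    epsilon: float = 1e-9

    def __post_init__(self) -> None:
        if self.n_iters < 0:
            raise ValueError("n_iters must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.dao and self.dao_start_iter < 1:
            raise ValueError("DAO needs at least one prior RL iteration")


def _shift1d(img: np.ndarray, s: float, axis: int) -> np.ndarray:
    """Bilinear translation along one axis with zero fill.

    out[i] = (1 - t) * in[i - f] + t * in[i - f - 1] with f = floor(s),
    t = s - f; this explicit gather is exactly adjoint to shifting by -s,
    which the projection operators rely on.
    """
    f = math.floor(s)
    t = s - f
    n = img.shape[axis]

    def gather(offset: int) -> np.ndarray:
        out = np.zeros_like(img)
        lo, hi = max(0, offset), min(n, n + offset)
        src = [slice(None)] * img.ndim
        dst = [slice(None)] * img.ndim
        dst[axis] = slice(lo, hi)
        src[axis] = slice(lo - offset, hi - offset)
        out[tuple(dst)] = img[tuple(src)]
        return out

    if t == 0.0:
        return gather(f)
    return (1.0 - t) * gather(f) + t * gather(f + 1)


def _shift2d(img: np.ndarray, dy: float, dx: float) -> np.ndarray:
    return _shift1d(_shift1d(img, dy, 0), dx, 1)


def _shift_views(stack: np.ndarray, wf: WavefrontMap,
                 sign: float) -> np.ndarray:
    out = np.empty_like(stack)
    a = stack.shape[0]
    for iu in range(a):
        for iv in range(a):
            dy, dx = wf.shifts[iu, iv]
            if dy == 0.0 and dx == 0.0:
                out[iu, iv] = stack[iu, iv]
            else:
                out[iu, iv] = _shift2d(stack[iu, iv], sign * dy, sign * dx)
    return out


def forward_project(volume: Volume3D, psf: PhaseSpacePSF,
                    wf: WavefrontMap | None = None,
                    scale: int = 3) -> SpatialAngularViews:
    """Project a volume to angular views: view(u,v) = sum_z vol[z] * k[u,v,z].

    Linear in the volume; when ``wf`` is given, each angle's view is
    additionally translated by its wavefront shift (bilinear, zero-padded).
    """
    nz = volume.shape[0]
    if nz != psf.n_z:
        raise ValueError("volume and PSF z-plane counts differ")
    a = psf.n_angles_side
    ny, nx = volume.shape[1:]
    views = np.zeros((a, a, ny, nx), dtype=np.float64)
    disk = psf.in_disk()
    for iu in range(a):
        for iv in range(a):
            if not disk[iu, iv]:
                continue
            acc = np.zeros((ny, nx))
            for iz in range(nz):
                acc += fftconvolve(volume.data[iz], psf.kernels[iu, iv, iz],
                                   mode="same")
            views[iu, iv] = acc
    if wf is not None:
        views = _shift_views(views, wf, sign=+1.0)
    return SpatialAngularViews(views, n_angles_side=a, scale=scale)


def back_project(views: SpatialAngularViews, psf: PhaseSpacePSF,
                 wf: WavefrontMap | None = None) -> np.ndarray:
    """Exact adjoint of :func:`forward_project` (correlation with kernels).

    Returns a raw (nz, ny, nx) array: as a linear adjoint it may carry
    negative values for non-physical inputs, so it is not wrapped in
    :class:`~slfm.lfsim.Volume3D`.
    """
    a = psf.n_angles_side
    if views.n_angles_side != a:
        raise ValueError("angle count mismatch")
    data = views.data.astype(np.float64, copy=False)
    if wf is not None:
        data = _shift_views(data, wf, sign=-1.0)
    ny, nx = data.shape[2:]
    vol = np.zeros((psf.n_z, ny, nx), dtype=np.float64)
    disk = psf.in_disk()
    for iu in range(a):
        for iv in range(a):
            if not disk[iu, iv]:
                continue
            flipped = psf.kernels[iu, iv, :, ::-1, ::-1]
            for iz in range(psf.n_z):
                vol[iz] += fftconvolve(data[iu, iv], flipped[iz], mode="same")
    return vol


def rl_step(volume: Volume3D, views: SpatialAngularViews,
            psf: PhaseSpacePSF, wf: WavefrontMap | None = None,
            epsilon: float = 1e-9,
            sensitivity: np.ndarray | None = None) -> Volume3D:
    """One multiplicative Richardson-Lucy update over all angular views.

    v <- v * backproject(measured / (forward(v) + eps)) / backproject(1).
    Non-negativity is preserved by the multiplicative form; a volume whose
    forward projection equals the measurements is a fixed point.

    ``sensitivity`` (backprojection of all-ones views) can be precomputed
    and reused across iterations.
    """
    meas = views.data
    if not np.any(meas):
        raise ValueError("all-zero measurement")
    pred = forward_project(volume, psf, wf, scale=views.scale).data
    ratio_views = SpatialAngularViews(meas / (pred + epsilon),
                                      views.n_angles_side, views.scale)
    correction = np.maximum(back_project(ratio_views, psf, wf), 0.0)
    if sensitivity is None:
        ones = SpatialAngularViews(np.ones_like(meas, dtype=np.float64),
                                   views.n_angles_side, views.scale)
        sensitivity = back_project(ones, psf, wf)
    upd = volume.data * correction / np.maximum(sensitivity, epsilon)
    return Volume3D(upd, volume.voxel_size_um, volume.wavelength_um)


def estimate_dao(views: SpatialAngularViews, volume: Volume3D,
                 psf: PhaseSpacePSF, upsample: int = 50,
                 zernike_max_order: int = 0,
                 wf_prev: WavefrontMap | None = None) -> WavefrontMap:
    """Estimate the per-angle wavefront shifts by subpixel registration.

    Each measured view is registered against the re-projection of the
    current volume estimate with subpixel cross-correlation; the resulting
    shift grid is gauge-fixed by removing its mean over in-pupil angles
    (a global tilt only translates the reconstruction).  Featureless views
    are flagged low-confidence and assigned zero shift.  With
    ``zernike_max_order`` >= 4 the raw shifts are smoothed by a fit to
    Zernike-mode pupil gradients (tilt excluded).

    Passing ``wf_prev`` refines an earlier estimate: the projection is
    rendered with the previous correction applied and the measured residual
    displacement is added to it, so repeated calls inside the
    reconstruction loop converge on the true map.
    """
    from skimage.registration import phase_cross_correlation

    pred = forward_project(volume, psf, wf_prev, scale=views.scale).data
    a = psf.n_angles_side
    disk = psf.in_disk()
    shifts = np.zeros((a, a, 2))
    confident = np.zeros((a, a), dtype=bool)
    for iu in range(a):
        for iv in range(a):
            if not disk[iu, iv]:
                continue
            m = views.data[iu, iv].astype(np.float64)
            p = pred[iu, iv]
            if m.std() < 1e-12 * (abs(m.mean()) + 1e-30) or p.std() == 0:
                continue  # featureless: zero shift, low confidence
            sh, _, _ = phase_cross_correlation(m - m.mean(), p - p.mean(),
                                               upsample_factor=upsample,
                                               normalization=None)
            shifts[iu, iv] = sh
            confident[iu, iv] = True
    if wf_prev is not None:
        shifts[disk] += wf_prev.shifts[disk]
    if confident.any():
        mean_tilt = shifts[confident].mean(axis=0)
        shifts[disk] -= mean_tilt  # gauge: remove global translation
    zern: dict[int, float] = {}
    residual = 0.0
    if zernike_max_order >= 4 and confident.any():
        zern, smoothed, residual = _fit_zernike_gradients(
            shifts, disk, confident, zernike_max_order)
        shifts = smoothed
    return WavefrontMap(shifts, zernike=zern, residual=residual,
                        confident=confident)


def _fit_zernike_gradients(shifts: np.ndarray, disk: np.ndarray,
                           confident: np.ndarray, max_order: int):
    """Least-squares fit of the shift field to Zernike pupil gradients."""
    a = shifts.shape[0]
    c = (a - 1) / 2.0
    coords = (np.arange(a) - c) / c
    ry, rx = np.meshgrid(coords, coords, indexing="ij")
    sel = disk & confident
    modes = list(range(4, max_order + 1))  # skip piston and tilt
    h = 1e-5
    cols = []
    rho = np.hypot(ry[sel], rx[sel])
    for j in modes:
        def w(dy, dx):
            yy, xx = ry[sel] + dy, rx[sel] + dx
            return zernike_noll(j, np.hypot(yy, xx), np.arctan2(yy, xx))
        gy = (w(h, 0) - w(-h, 0)) / (2 * h)
        gx = (w(0, h) - w(0, -h)) / (2 * h)
        cols.append(np.concatenate([gy, gx]))
    design = np.stack(cols, axis=1)
    target = np.concatenate([shifts[sel, 0], shifts[sel, 1]])
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    fit = design @ coef
    n = sel.sum()
    smoothed = np.zeros_like(shifts)
    smoothed[sel, 0] = fit[:n]
    smoothed[sel, 1] = fit[n:]
    residual = float(np.sqrt(np.mean((target - fit) ** 2)))
    return dict(zip(modes, coef.tolist())), smoothed, residual


def reconstruct(views: SpatialAngularViews, psf: PhaseSpacePSF,
                cfg: ReconstructionConfig | None = None
                ) -> tuple[Volume3D, WavefrontMap]:
    """Richardson-Lucy iterative tomography with optional interleaved DAO.

    Starts from a uniform volume carrying the measured energy, runs
    ``cfg.n_iters`` multiplicative updates, and (when ``cfg.dao``) estimates
    the wavefront map after ``dao_start_iter`` iterations, refreshing every
    ``dao_every``; all subsequent updates use the corrected model.
    """
    cfg = cfg or ReconstructionConfig()
    a = psf.n_angles_side
    if views.n_angles_side != a:
        raise ValueError("views/PSF angle count mismatch")
    nz = psf.n_z
    ny, nx = views.data.shape[2:]
    total = float(views.data.sum())
    init = max(total, 1.0) / (nz * ny * nx)
    dz = float(np.mean(np.diff(psf.z_planes_um))) if nz > 1 else 1.0
    volume = Volume3D(np.full((nz, ny, nx), init),
                      (abs(dz), psf.pixel_size_um, psf.pixel_size_um),
                      psf.wavelength_um)
    wf: WavefrontMap | None = None
    sens_plain: np.ndarray | None = None
    for it in range(cfg.n_iters):
        if (cfg.dao and it >= cfg.dao_start_iter
                and (it - cfg.dao_start_iter) % cfg.dao_every == 0):
            wf = estimate_dao(views, volume, psf,
                              zernike_max_order=cfg.zernike_max_order,
                              wf_prev=wf)
        if wf is None:
            if sens_plain is None:
                ones = SpatialAngularViews(
                    np.ones_like(views.data, dtype=np.float64), a, views.scale)
                sens_plain = back_project(ones, psf)
            volume = rl_step(volume, views, psf, None, cfg.epsilon,
                             sensitivity=sens_plain)
        else:
            volume = rl_step(volume, views, psf, wf, cfg.epsilon)
    if wf is None:
        wf = WavefrontMap(np.zeros((a, a, 2)))
    return volume, wf
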