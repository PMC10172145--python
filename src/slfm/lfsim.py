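"""Synthetic scanning light-field microscopy acquisitions.

This module generates the objects and raw measurements every downstream
stage consumes: 3D bead and tubulin phantoms, a phase-space point-spread
function (one 2D kernel per pupil angle and depth), Zernike-parameterised
pupil aberrations, 3x3 sub-pitch galvo scan series, and a mixed
Poisson-Gaussian camera noise model.

The phase-space PSF here is a documented approximation, not a wave-optics
derivation: under the ``geometric`` model a point source at depth z appears
in angular view (u, v) laterally shifted in proportion to z*tan(theta_uv)
and blurred by a Gaussian whose width grows linearly with |z|; the
``quasi_wave`` model adds a diffraction floor sigma0 = 0.61*lambda/NA.
A rigorous externally computed PSF can be loaded from file instead
(:func:`load_psf`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "Volume3D",
    "PhaseSpacePSF",
    "ZernikeWavefront",
    "NoiseParams",
    "ScanSeries",
    "generate_beads",
    "generate_tubulins",
    "build_psf",
    "apply_aberration",
    "render_scan_series",
    "add_mixed_noise",
    "save_psf",
    "load_psf",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...

# refractive index of standard immersion oil; overridable in build_psf
DEFAULT_MEDIUM_INDEX = 1.518


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Volume3D:
    """Non-negative 3D intensity grid ``data[z][y][x]``.

    Parameters
    ----------
    data:
        Intensity values, arbitrary units, all finite and >= 0.
    voxel_size_um:
        (dz, dy, dx) voxel pitch in micrometres.
    wavelength_um:
        Emission wavelength in micrometres.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]
    wavelength_um: float = 0.525

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume must be a non-empty 3D array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if np.any(self.data < 0):
            raise ValueError("volume intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def total_flux(self) -> float:
        return float(self.data.sum())


@dataclass
class PhaseSpacePSF:
    """Bank of 2D kernels indexed by (angle u, angle v, depth z).

    ``kernels`` has shape (a, a, nz, k, k) with odd kernel side k.  Angles
    outside the pupil disk carry all-zero kernels; for every depth the total
    energy summed over all angles is 1 (flux conservation through the
    forward projector).
    """

    kernels: np.ndarray
    n_angles_side: int
    z_planes_um: np.ndarray
    na: float
    pixel_size_um: float
    wavelength_um: float
    model: str = "geometric"
    medium_index: float = DEFAULT_MEDIUM_INDEX

    def __post_init__(self) -> None:
        self.kernels = np.asarray(self.kernels, dtype=np.float64)
        self.z_planes_um = np.asarray(self.z_planes_um, dtype=np.float64)
        a = self.n_angles_side
        if self.kernels.shape[:3] != (a, a, len(self.z_planes_um)):
            raise ValueError("kernel bank shape inconsistent with angles/z")
        k = self.kernels.shape[-1]
        if self.kernels.shape[-2] != k or k % 2 == 0:
            raise ValueError("kernel support must be square and odd-sized")
        if np.any(self.kernels < 0):
            raise ValueError("kernels must be non-negative")

    @property
    def n_z(self) -> int:
        return len(self.z_planes_um)

    @property
    def kernel_px(self) -> int:
        return self.kernels.shape[-1]

    def pupil_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Normalised pupil coordinates (rho_y, rho_x) per angle index."""
        a = self.n_angles_side
        c = (a - 1) / 2.0
        r = (np.arange(a) - c) / c
        return np.meshgrid(r, r, indexing="ij")

    def in_disk(self) -> np.ndarray:
        ry, rx = self.pupil_coords()
        return ry**2 + rx**2 <= 1.0 + 1e-12

    def angle_tangents(self) -> tuple[np.ndarray, np.ndarray]:
        """tan(theta) along y and x per angle; NaN-free (0 outside disk)."""
        ry, rx = self.pupil_coords()
        s = self.na / self.medium_index
        sy, sx = ry * s, rx * s
        with np.errstate(invalid="ignore"):
            denom = np.sqrt(np.maximum(1.0 - sy**2 - sx**2, 1e-9))
        mask = self.in_disk()
        return np.where(mask, sy / denom, 0.0), np.where(mask, sx / denom, 0.0)


@dataclass
class ZernikeWavefront:
    """Pupil wavefront as Noll-indexed orthonormal Zernike coefficients.

    ``coeffs`` maps Noll index j (>= 1) to mode amplitude in wavelengths.
    Piston (j = 1) carries no lateral information and is excluded from the
    RMS, which for orthonormal modes is the root-sum-square of coefficients.
    """

    coeffs: dict[int, float] = field(default_factory=dict)
    max_order: int = 36

    def __post_init__(self) -> None:
        for j in self.coeffs:
            if j < 1:
                raise ValueError("Noll indices start at 1")
            if j > self.max_order:
                raise ValueError(f"Zernike mode {j} above configured max order")

    @property
    def rms_wavelengths(self) -> float:
        return math.sqrt(sum(c * c for j, c in self.coeffs.items() if j >= 2))

    def evaluate(self, rho_y: np.ndarray, rho_x: np.ndarray) -> np.ndarray:
        rho = np.hypot(rho_y, rho_x)
        theta = np.arctan2(rho_y, rho_x)
        w = np.zeros_like(rho, dtype=np.float64)
        for j, c in self.coeffs.items():
            if c != 0.0:
                w += c * zernike_noll(j, rho, theta)
        return w

    def gradient(self, rho_y: float, rho_x: float, h: float = 1e-5
                 ) -> tuple[float, float]:
        """(dW/drho_y, dW/drho_x) by central differences, wavelengths/unit."""
        ry = np.array([rho_y + h, rho_y - h, rho_y, rho_y])
        rx = np.array([rho_x, rho_x, rho_x + h, rho_x - h])
        w = self.evaluate(ry, rx)
        return float((w[0] - w[1]) / (2 * h)), float((w[2] - w[3]) / (2 * h))


def noll_to_nm(j: int) -> tuple[int, int]:
    """Convert Noll index j >= 1 to (radial order n, azimuthal frequency m)."""
    if j < 1:
        raise ValueError("Noll index must be >= 1")
    n = 0
    j1 = j - 1
    while j1 > n:
        n += 1
        j1 -= n
    m = (-1) ** j * ((n % 2) + 2 * ((j1 + ((n + 1) % 2)) // 2))
    return n, m


def zernike_noll(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Orthonormal Zernike polynomial Z_j over the unit disk (Noll index)."""
    n, m = noll_to_nm(j)
    am = abs(m)
    rho = np.asarray(rho, dtype=np.float64)
    r = np.zeros_like(rho)
    for s in range((n - am) // 2 + 1):
        coef = ((-1) ** s * math.factorial(n - s)
                / (math.factorial(s)
                   * math.factorial((n + am) // 2 - s)
                   * math.factorial((n - am) // 2 - s)))
        r += coef * rho ** (n - 2 * s)
    if m == 0:
        norm = math.sqrt(n + 1.0)
        return norm * r
    norm = math.sqrt(2.0 * (n + 1.0))
    if m > 0:
        return norm * r * np.cos(am * theta)
    return norm * r * np.sin(am * theta)


@dataclass
class NoiseParams:
    """Mixed Poisson-Gaussian camera model parameters.

    ``photon_max`` is the expected photon count at the brightest pixel,
    ``gauss_var`` the additive read-noise variance in sensor digital units
    at the given bit depth (the convention used throughout this package).
    """

    photon_max: float = 30.0
    gauss_var: float = 5.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photon_max <= 0:
            raise ValueError("photon_max must be > 0")
        if self.gauss_var < 0:
            raise ValueError("gauss_var must be >= 0")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be one of 8, 12, 16")


_SCAN_STEPS = (-1.0 / 3.0, 0.0, 1.0 / 3.0)


@dataclass
class ScanSeries:
    """Ordered 3x3 sub-pitch galvo scan: 9 raw frames with their offsets.

    Offsets are (dy, dx) in units of the microlens pitch, row-major over the
    {-1/3, 0, +1/3}^2 grid; the zero-offset frame sits at index 4.
    """

    frames: list
    offsets: list[tuple[float, float]]
    scan_factor: int = 3

    def __post_init__(self) -> None:
        n = self.scan_factor**2
        if len(self.frames) != n or len(self.offsets) != n:
            raise ValueError(f"scan series must hold exactly {n} frames")
        want = {(round(dy, 6), round(dx, 6))
                for dy in _SCAN_STEPS for dx in _SCAN_STEPS}
        got = {(round(dy, 6), round(dx, 6)) for dy, dx in self.offsets}
        if got != want:
            raise ValueError("offsets must cover the {-1/3,0,+1/3}^2 grid "
                             "exactly once")


# ---------------------------------------------------------------------------
# sample generators
# ---------------------------------------------------------------------------

def generate_beads(n_beads: int, shape: tuple[int, int, int],
                   bead_fwhm_um: float = 0.3,
                   voxel_size_um: tuple[float, float, float] = (0.2, 0.1, 0.1),
                   wavelength_um: float = 0.525,
                   seed: int = 0) -> Volume3D:
    """Volume of isotropic Gaussian beads at random sub-voxel positions.

    Each bead carries unit integrated flux on the grid.  Sub-diffraction
    beads (e.g. 100 nm) are represented by their flux: the rendered width is
    ``bead_fwhm_um``, standing for the system-side blur floor, not the bead
    diameter.  Centers closer than one FWHM to any border are
    rejection-resampled so flux bookkeeping stays exact.
    """
    if n_beads < 0:
        raise ValueError("n_beads must be >= 0")
    if min(shape) < 1 or bead_fwhm_um <= 0:
        raise ValueError("invalid shape or bead FWHM")
    rng = np.random.default_rng(seed)
    data = np.zeros(shape, dtype=np.float64)
    sigma_um = bead_fwhm_um / FWHM_PER_SIGMA
    sig = np.array([sigma_um / v for v in voxel_size_um])  # voxels, per axis
    margin = np.array([bead_fwhm_um / v for v in voxel_size_um])
    lo = margin
    hi = np.array(shape) - 1 - margin
    if np.any(hi < lo):
        raise ValueError("volume too small for the requested bead margin")
    for _ in range(n_beads):
        center = lo + rng.random(3) * (hi - lo)
        _splat_gaussian(data, center, sig, flux=1.0)
    return Volume3D(data, voxel_size_um, wavelength_um)


def _splat_gaussian(data: np.ndarray, center: np.ndarray,
                    sigma_vox: np.ndarray, flux: float) -> None:
    """Add a Gaussian blob of exactly `flux` integrated grid mass in place."""
    half = np.maximum(np.ceil(4 * sigma_vox).astype(int), 1)
    sl, grids = [], []
    for ax in range(3):
        a = max(int(math.floor(center[ax])) - half[ax], 0)
        b = min(int(math.ceil(center[ax])) + half[ax] + 1, data.shape[ax])
        sl.append(slice(a, b))
        grids.append(np.arange(a, b) - center[ax])
    gz = np.exp(-0.5 * (grids[0] / sigma_vox[0]) ** 2)
    gy = np.exp(-0.5 * (grids[1] / sigma_vox[1]) ** 2)
    gx = np.exp(-0.5 * (grids[2] / sigma_vox[2]) ** 2)
    blob = gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    s = blob.sum()
    if s > 0:
        data[tuple(sl)] += blob * (flux / s)


def generate_tubulins(n_filaments: int, shape: tuple[int, int, int],
                      radius_um: float = 0.5,
                      voxel_size_um: tuple[float, float, float] = (0.2, 0.1, 0.1),
                      wavelength_um: float = 0.525,
                      seed: int = 0,
                      step_um: float | None = None,
                      bend: float = 0.15) -> Volume3D:
    """Volume of smooth random-walk tubes of Gaussian cross-section.

    Each filament is a persistent random walk; points along the path are
    splatted as Gaussians whose cross-section FWHM equals the tube diameter
    ``2 * radius_um`` (so a profile across a filament measures ~2r).
    """
    if n_filaments < 0:
        raise ValueError("n_filaments must be >= 0")
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    rng = np.random.default_rng(seed)
    data = np.zeros(shape, dtype=np.float64)
    vs = np.asarray(voxel_size_um)
    extent = np.array(shape) * vs
    sigma_um = 2.0 * radius_um / FWHM_PER_SIGMA
    sig = sigma_um / vs
    if step_um is None:
        step_um = min(voxel_size_um) / 2.0
    for _ in range(n_filaments):
        pos = extent * (0.15 + 0.7 * rng.random(3))
        d = rng.normal(size=3)
        d[0] *= 0.3  # mostly lateral filaments, like mounted specimens
        d /= np.linalg.norm(d)
        n_steps = int(1.5 * max(extent) / step_um)
        for _ in range(n_steps):
            vox = pos / vs
            if np.all(vox > 0) and np.all(vox < np.array(shape) - 1):
                _splat_gaussian(data, vox, sig, flux=step_um)
            d = d + bend * rng.normal(size=3) * math.sqrt(step_um)
            d /= np.linalg.norm(d)
            pos = pos + d * step_um
            if np.any(pos < -0.1 * extent) or np.any(pos > 1.1 * extent):
                break
    return Volume3D(data, voxel_size_um, wavelength_um)


# ---------------------------------------------------------------------------
# phase-space PSF
# ---------------------------------------------------------------------------

def build_psf(na: float, wavelength_um: float, n_angles_side: int,
              z_planes_um, pixel_size_um: float,
              model: str = "geometric",
              kernel_px: int | None = None,
              medium_index: float = DEFAULT_MEDIUM_INDEX) -> PhaseSpacePSF:
    """Build the bank of per-(angle, depth) kernels for the forward model.

    Pupil-to-angle mapping: angle index (u, v) sits on a uniform grid over
    the pupil disk; indices outside the NA circle get zero kernels.  Kernels
    are normalised so that for each depth the energy summed over all angles
    is exactly 1.

    Parameters
    ----------
    pixel_size_um:
        Lateral sampling of the view grid the kernels act on (use the fine,
        scale-3 pitch when projecting scan-resolved views).
    kernel_px:
        Odd kernel side; computed from the maximal disparity and blur when
        omitted.
    """
    z_planes_um = np.asarray(z_planes_um, dtype=np.float64)
    if z_planes_um.size == 0:
        raise ValueError("z plane list must not be empty")
    if not 0 < na < medium_index:
        raise ValueError("need 0 < NA < medium refractive index")
    if model not in ("geometric", "quasi_wave"):
        raise ValueError(f"unknown PSF model {model!r}")

    a = n_angles_side
    c = (a - 1) / 2.0
    rho_1d = (np.arange(a) - c) / c
    ry, rx = np.meshgrid(rho_1d, rho_1d, indexing="ij")
    disk = ry**2 + rx**2 <= 1.0 + 1e-12

    s = na / medium_index
    with np.errstate(invalid="ignore"):
        denom = np.sqrt(np.maximum(1.0 - (ry * s) ** 2 - (rx * s) ** 2, 1e-9))
    tan_y = np.where(disk, ry * s / denom, 0.0)
    tan_x = np.where(disk, rx * s / denom, 0.0)

    # per-angle defocus blur: a sub-aperture of angular half-width ~NA/a
    sub_s = s / a
    blur_slope = sub_s / math.sqrt(max(1.0 - sub_s**2, 1e-9))  # um blur / um z
    sigma_floor_um = 0.5 * pixel_size_um
    if model == "quasi_wave":
        sigma_floor_um = max(sigma_floor_um, 0.61 * wavelength_um / na)

    zmax = float(np.max(np.abs(z_planes_um))) if z_planes_um.size else 0.0
    if kernel_px is None:
        max_shift = zmax * float(np.max(np.hypot(tan_y, tan_x)))
        max_sigma = sigma_floor_um + blur_slope * zmax
        kernel_px = 2 * int(math.ceil((max_shift + 4 * max_sigma)
                                      / pixel_size_um)) + 3
    if kernel_px % 2 == 0:
        raise ValueError("kernel support must be odd-sized")

    half = kernel_px // 2
    coord = np.arange(-half, half + 1, dtype=np.float64)
    yy, xx = np.meshgrid(coord, coord, indexing="ij")
    n_in = int(disk.sum())

    kernels = np.zeros((a, a, len(z_planes_um), kernel_px, kernel_px))
    for iz, z in enumerate(z_planes_um):
        sigma_px = (sigma_floor_um + blur_slope * abs(z)) / pixel_size_um
        for iu in range(a):
            for iv in range(a):
                if not disk[iu, iv]:
                    continue
                cy = z * tan_y[iu, iv] / pixel_size_um
                cx = z * tan_x[iu, iv] / pixel_size_um
                g = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2)
                           / (2 * sigma_px**2))
                tot = g.sum()
                if tot <= 0:
                    raise ValueError("kernel support too small for disparity")
                kernels[iu, iv, iz] = g / (tot * n_in)
    return PhaseSpacePSF(kernels, a, z_planes_um, na, pixel_size_um,
                         wavelength_um, model=model,
                         medium_index=medium_index)


def apply_aberration(psf: PhaseSpacePSF, wf: ZernikeWavefront) -> PhaseSpacePSF:
    """Shift each angle's kernels by the local pupil gradient of the wavefront.

    Paraxial model: a wavefront slope dW/drho (wavelengths per unit pupil
    radius) at the sub-aperture of angle (u, v) displaces that view by
    ``lambda * dW/drho / (2 * NA)`` micrometres.  Kernel energies are
    preserved (each shifted kernel is rescaled to its original mass).
    """
    from scipy.ndimage import shift as nd_shift

    scale = psf.wavelength_um / (2.0 * psf.na * psf.pixel_size_um)
    out = psf.kernels.copy()
    ry, rx = psf.pupil_coords()
    disk = psf.in_disk()
    a = psf.n_angles_side
    for iu in range(a):
        for iv in range(a):
            if not disk[iu, iv]:
                continue
            gy, gx = wf.gradient(ry[iu, iv], rx[iu, iv])
            dy, dx = scale * gy, scale * gx
            if dy == 0.0 and dx == 0.0:
                continue
            for iz in range(psf.n_z):
                k = psf.kernels[iu, iv, iz]
                e0 = k.sum()
                sh = nd_shift(k, (dy, dx), order=1, mode="constant", cval=0.0)
                e1 = sh.sum()
                if e1 < 0.95 * e0:
                    raise ValueError(
                        "aberration shift pushes kernel energy off support; "
                        "increase kernel_px")
                out[iu, iv, iz] = sh * (e0 / e1)
    return PhaseSpacePSF(out, psf.n_angles_side, psf.z_planes_um, psf.na,
                         psf.pixel_size_um, psf.wavelength_um,
                         model=psf.model, medium_index=psf.medium_index)


def save_psf(psf: PhaseSpacePSF, path) -> None:
    """Persist a PSF bank (numpy archive + YAML sidecar metadata)."""
    np.savez_compressed(str(path), kernels=psf.kernels,
                        z_planes_um=psf.z_planes_um)
    meta = {"n_angles_side": psf.n_angles_side, "na": psf.na,
            "pixel_size_um": psf.pixel_size_um,
            "wavelength_um": psf.wavelength_um, "model": psf.model,
            "medium_index": psf.medium_index}
    sidecar = str(path) + ".yaml" if not str(path).endswith(".npz") \
        else str(path)[:-4] + ".yaml"
    with open(sidecar, "w") as fh:
        yaml.safe_dump(meta, fh)


def load_psf(path) -> PhaseSpacePSF:
    """Load a PSF bank saved by :func:`save_psf` (or an external one in the
    same layout), enabling rigorous externally computed PSFs to be plugged in."""
    p = str(path)
    if not p.endswith(".npz"):
        p = p + ".npz"
    arch = np.load(p)
    with open(p[:-4] + ".yaml") as fh:
        meta = yaml.safe_load(fh)
    return PhaseSpacePSF(arch["kernels"], meta["n_angles_side"],
                         arch["z_planes_um"], meta["na"],
                         meta["pixel_size_um"], meta["wavelength_um"],
                         model=meta.get("model", "external"),
                         medium_index=meta.get("medium_index",
                                               DEFAULT_MEDIUM_INDEX))


# ---------------------------------------------------------------------------
# acquisition rendering
# ---------------------------------------------------------------------------

def render_scan_series(volume: Volume3D, psf: PhaseSpacePSF,
                       scan_factor: int = 3,
                       pixel_aperture: bool = True) -> ScanSeries:
    """Render the 9-frame 3x3 sub-pitch scan of a volume (noiseless).

    The volume's lateral grid is the fine (scale-3) view grid; the PSF must
    be sampled on that same grid.  Every view sample integrates light over
    the full microlens aperture (one lens pitch), modelled as a 3x3 box
    filter on the fine grid (``pixel_aperture``); each galvo offset then
    selects one of the nine sub-phases, which is packed back into a raw
    macro-pixel sensor frame.  Frame order is row-major over the offset
    grid, so the zero-offset "middle" frame is index 4.
    """
    from scipy.ndimage import uniform_filter

    from . import realign, tomo

    if scan_factor != 3:
        raise ValueError("only 3x3 scanning is supported")
    nz, ny, nx = volume.shape
    if nz != psf.n_z:
        raise ValueError("volume z planes must match PSF z planes")
    if ny % 3 or nx % 3 or ny != nx:
        raise ValueError("lateral volume size must be square and divisible "
                         "by the scan factor")
    hr = tomo.forward_project(volume, psf).data  # (a, a, ny, nx) fine views
    if pixel_aperture:
        hr = uniform_filter(hr, size=(1, 1, 3, 3), mode="constant") * 9.0
    a = psf.n_angles_side
    frames, offsets = [], []
    for oy in (-1, 0, 1):
        for ox in (-1, 0, 1):
            sub = hr[:, :, oy + 1::3, ox + 1::3]
            views = realign.SpatialAngularViews(sub.copy(), n_angles_side=a,
                                                scale=1)
            frames.append(realign.views_to_raw(views))
            offsets.append((oy / 3.0, ox / 3.0))
    return ScanSeries(frames, offsets, scan_factor=3)


def add_mixed_noise(image: np.ndarray, params: NoiseParams,
                    peak_digital: float | None = None) -> np.ndarray:
    """Apply the mixed Poisson-Gaussian camera model to a sensor frame.

    Order: scale the frame so its maximum maps to ``photon_max`` expected
    photons -> Poisson sample -> apply the digital gain -> add Gaussian read
    noise of variance ``gauss_var`` (digital units) -> clip to the bit depth
    -> quantize.  Deterministic given ``params.seed``.

    ``peak_digital`` sets where the clean maximum lands in digital units;
    the default is unit camera gain (one count per photon, so 30 photons ->
    30 counts, on which a read-noise variance of 5 is severe) capped at half
    the sensor full scale for very bright acquisitions.  The clean
    comparator for error analysis is ``image * peak_digital / image.max()``.
    """
    image = np.asarray(image, dtype=np.float64)
    if np.any(image < 0):
        raise ValueError("sensor frame must be non-negative")
    rng = np.random.default_rng(params.seed)
    full_scale = 2**params.bit_depth - 1
    if peak_digital is None:
        peak_digital = min(params.photon_max, (full_scale + 1) / 2.0)
    peak = image.max()
    if peak == 0:
        warnings.warn("all-zero frame: returning quantized Gaussian noise "
                      "only", RuntimeWarning, stacklevel=2)
        noisy = rng.normal(0.0, math.sqrt(params.gauss_var), image.shape)
        return np.clip(np.rint(noisy), 0, full_scale).astype(np.uint16)
    photons = image * (params.photon_max / peak)
    digital = rng.poisson(photons) * (peak_digital / params.photon_max)
    if params.gauss_var > 0:
        digital = digital + rng.normal(0.0, math.sqrt(params.gauss_var),
                                       image.shape)
    return np.clip(np.rint(digital), 0, full_scale).astype(np.uint16)
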