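"""Quantitative image-quality and resolution metrics.

Implements the evaluation suite used throughout the package: signal-to-noise
ratio in dB, structural similarity (2D and a 3D variant that treats the
angular dimension as depth), Pearson correlation, single-image decorrelation
analysis (cut-off frequency k_c), Fourier ring correlation (FRC) resolution
at the 1/7 threshold, and Gaussian-fit full width at half maximum.

Conventions: images compared by SSIM are assumed normalised to [0, 1] so
the dynamic range L is 1; SSIM uses Gaussian windows of size 11 (sigma 1.5)
in valid mode; spatial frequencies are normalised so the Nyquist frequency
is 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import fftconvolve

__all__ = [
    "MetricPair",
    "DecorrelationCurve",
    "snr_db",
    "ssim",
    "pearson",
    "decorrelation_kc",
    "frc_curve",
    "frc_resolution",
    "fwhm_gaussian",
    "FWHM_PER_SIGMA",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class MetricPair:
    """A (ground truth X, estimate Y) pair with matching shapes."""

    X: np.ndarray
    Y: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.Y = np.asarray(self.Y, dtype=np.float64)
        if self.X.shape != self.Y.shape:
            raise ValueError("X and Y must share a shape")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.Y))):
            raise ValueError("non-finite values in metric pair")

    def normalized_copy(self) -> "MetricPair":
        """Scale both members jointly so X spans [0, 1] (L = 1)."""
        if self.normalized:
            return self
        lo, hi = self.X.min(), self.X.max()
        if hi <= lo:
            raise ValueError("cannot normalize a constant ground truth")
        return MetricPair((self.X - lo) / (hi - lo),
                          (self.Y - lo) / (hi - lo), normalized=True)


@dataclass
class DecorrelationCurve:
    """d(r) over mask radii (normalised frequency, Nyquist = 1) and its
    peak radius k_c."""

    r_grid: np.ndarray
    d: np.ndarray
    k_c: float


def snr_db(pair: MetricPair) -> float:
    """SNR = 10 log10(||X||^2 / ||X - Y||^2) in dB; +inf when X == Y."""
    num = float(np.sum(pair.X**2))
    if num == 0:
        raise ValueError("ground truth is all zero")
    den = float(np.sum((pair.X - pair.Y) ** 2))
    if den == 0:
        return math.inf
    return 10.0 * math.log10(num / den)


def _gaussian_window(ndim: int, size: int = 11, sigma: float = 1.5
                     ) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g1 = np.exp(-0.5 * (ax / sigma) ** 2)
    g1 /= g1.sum()
    w = g1
    for _ in range(ndim - 1):
        w = np.multiply.outer(w, g1)
    return w


def ssim(pair: MetricPair, mode: str = "2d", win_size: int = 11,
         sigma: float = 1.5, L: float = 1.0) -> float:
    """Mean structural similarity with Gaussian windows (valid mode).

    SSIM = (2 mu_x mu_y + C1)(2 sigma_xy + C2) /
           ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2)),
    C1 = (0.01 L)^2, C2 = (0.03 L)^2, computed in local Gaussian windows of
    size 11 and standard deviation 1.5, then averaged.  ``mode='3d'`` uses
    11^3 windows; 4D angular views (u, v, y, x) are first reshaped to a
    (y, x, angle) stack, angles in row-major spatial-proximity order.
    """
    X, Y = pair.X, pair.Y
    if mode == "3d" and X.ndim == 4:
        a = X.shape[0]
        X = X.transpose(2, 3, 0, 1).reshape(X.shape[2], X.shape[3], a * a)
        Y = Y.transpose(2, 3, 0, 1).reshape(Y.shape[2], Y.shape[3], a * a)
    elif mode == "2d" and X.ndim != 2:
        raise ValueError("2d mode expects 2D images")
    elif mode not in ("2d", "3d"):
        raise ValueError("mode must be '2d' or '3d'")
    if min(X.shape) < win_size:
        raise ValueError("window larger than image")
    w = _gaussian_window(X.ndim, win_size, sigma)

    def smooth(img):
        return fftconvolve(img, w, mode="valid")

    mu_x, mu_y = smooth(X), smooth(Y)
    sxx = smooth(X * X) - mu_x**2
    syy = smooth(Y * Y) - mu_y**2
    sxy = smooth(X * Y) - mu_x * mu_y
    c1, c2 = (0.01 * L) ** 2, (0.03 * L) ** 2
    num = (2 * mu_x * mu_y + c1) * (2 * sxy + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (sxx + syy + c2)
    return float(np.mean(num / den))


def pearson(pair: MetricPair) -> float:
    """Pearson correlation coefficient R between the flattened signals."""
    x = pair.X.ravel()
    y = pair.Y.ravel()
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("Pearson undefined for constant input")
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def decorrelation_kc(image: np.ndarray, n_radii: int = 50,
                     r_min: float = 0.02) -> DecorrelationCurve:
    """Single-image decorrelation analysis.

    With I(k) the image spectrum and I_n(k) = I(k)/|I(k)| its normalised
    form, the masked cross-correlation coefficient is

        d(r) = Re{ sum I(k) conj(I_n(k)) M(k; r) }
               / sqrt( sum |I(k)|^2 * sum |I_n(k) M(k; r)|^2 ),

    where M(k; r) is the binary disk of radius r (normalised frequency,
    Nyquist = 1).  The cut-off k_c is the radius of the highest peak of
    d(r); ties resolve to the largest radius.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("decorrelation analysis expects a 2D image")
    if image.max() == image.min():
        raise ValueError("constant image has no spectral content")
    spec = np.fft.fftshift(np.fft.fft2(image - image.mean()))
    mag = np.abs(spec)
    with np.errstate(invalid="ignore", divide="ignore"):
        spec_n = np.where(mag > 0, spec / mag, 0.0)
    fy = np.fft.fftshift(np.fft.fftfreq(image.shape[0])) / 0.5
    fx = np.fft.fftshift(np.fft.fftfreq(image.shape[1])) / 0.5
    rr = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
    cross = np.real(spec * np.conj(spec_n))
    denom_left = float(np.sum(mag**2))
    r_grid = np.linspace(r_min, 1.0, n_radii)
    d = np.zeros(n_radii)
    for i, r in enumerate(r_grid):
        mask = rr <= r
        # I_n has unit modulus wherever defined, so sum|I_n M|^2 counts the mask
        denom_right = float(np.sum((np.abs(spec_n) ** 2)[mask]))
        if denom_right == 0:
            continue
        d[i] = float(np.sum(cross[mask])) / math.sqrt(denom_left * denom_right)
    peak = float(np.max(d))
    k_c = float(r_grid[np.flatnonzero(d >= peak - 1e-12)[-1]])
    return DecorrelationCurve(r_grid, d, k_c)


def frc_curve(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fourier ring correlation per 1-pixel-wide frequency ring.

    Returns (ring center frequencies normalised to Nyquist = 1, FRC values).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 2:
        raise ValueError("FRC expects two 2D images of equal shape")
    fx_ = np.fft.fftshift(np.fft.fft2(x - x.mean()))
    fy_ = np.fft.fftshift(np.fft.fft2(y - y.mean()))
    n = min(x.shape)
    gy = np.fft.fftshift(np.fft.fftfreq(x.shape[0]))
    gx = np.fft.fftshift(np.fft.fftfreq(x.shape[1]))
    rr = np.hypot(*np.meshgrid(gy, gx, indexing="ij"))
    ring_idx = np.rint(rr * n).astype(int)  # 1 frequency-pixel rings
    n_rings = n // 2
    num = np.zeros(n_rings)
    d1 = np.zeros(n_rings)
    d2 = np.zeros(n_rings)
    flat = ring_idx.ravel()
    valid = flat < n_rings
    np.add.at(num, flat[valid], np.real(fx_ * np.conj(fy_)).ravel()[valid])
    np.add.at(d1, flat[valid], (np.abs(fx_) ** 2).ravel()[valid])
    np.add.at(d2, flat[valid], (np.abs(fy_) ** 2).ravel()[valid])
    with np.errstate(invalid="ignore", divide="ignore"):
        frc = np.where((d1 > 0) & (d2 > 0), num / np.sqrt(d1 * d2), 0.0)
    frc[0] = 1.0  # DC ring is degenerate after mean subtraction
    freqs = (np.arange(n_rings) / n) / 0.5  # Nyquist = 1
    return freqs, frc


def frc_resolution(pair: MetricPair, pixel_size: float | None = None,
                   threshold: float = 1.0 / 7.0):
    """FRC cut-off: first crossing below the 1/7 threshold.

    The curve is not smoothed; the crossing is linearly interpolated
    between adjacent rings.  Returns the cut-off in normalised frequency
    (Nyquist = 1), or ``(cutoff, resolution_physical)`` when ``pixel_size``
    is given (resolution = 2 * pixel_size / cutoff).
    """
    freqs, frc = frc_curve(pair.X, pair.Y)
    cutoff = freqs[-1]  # no crossing: resolution at Nyquist
    for i in range(1, len(frc)):
        if frc[i] < threshold <= frc[i - 1]:
            f0, f1 = freqs[i - 1], freqs[i]
            c0, c1 = frc[i - 1], frc[i]
            cutoff = f0 + (threshold - c0) * (f1 - f0) / (c1 - c0)
            break
        if i == 1 and frc[i - 1] < threshold:
            cutoff = freqs[0] if freqs[0] > 0 else freqs[1]
            break
    cutoff = float(cutoff)
    if pixel_size is None:
        return cutoff
    return cutoff, 2.0 * pixel_size / cutoff


def _gauss_model(x, offset, amplitude, center, sigma):
    return offset + amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def fwhm_gaussian(profile: np.ndarray, pixel_size: float = 1.0) -> float:
    """FWHM of a single-peaked profile from a least-squares Gaussian fit.

    Fits offset + amplitude * exp(-(x - c)^2 / (2 sigma^2)) and returns
    2 sqrt(2 ln 2) * sigma * pixel_size.  A 2D/3D input is reduced to the
    1D profile through its maximum along the last axis.
    """
    profile = np.asarray(profile, dtype=np.float64)
    if profile.ndim > 1:
        peak = np.unravel_index(np.argmax(profile), profile.shape)
        profile = profile[peak[:-1]]
    if profile.size < 5:
        raise ValueError("profile too short for a Gaussian fit")
    if profile.max() == profile.min():
        raise ValueError("flat profile has no peak to fit")
    x = np.arange(profile.size, dtype=np.float64)
    amp0 = profile.max() - profile.min()
    c0 = float(np.argmax(profile))
    above = profile - profile.min() > amp0 / 2
    sig0 = max(float(above.sum()) / FWHM_PER_SIGMA, 0.5)
    try:
        popt, _ = curve_fit(_gauss_model, x, profile,
                            p0=[profile.min(), amp0, c0, sig0],
                            maxfev=10000)
    except RuntimeError as err:
        raise ValueError("Gaussian fit did not converge") from err
    sigma = abs(popt[3])
    return FWHM_PER_SIGMA * sigma * pixel_size
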