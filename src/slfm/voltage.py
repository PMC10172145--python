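"""Voltage-imaging trace analysis.

Works on ROI-mean fluorescence traces from reconstructed time series (the
paper-scale acquisitions run at 500 volumes per second): Delta-F/F0 with the
baseline taken as the mean over the entire series, spike detection as local
peaks above a threshold after subtracting a 40 ms median-filtered baseline,
per-spike amplitude/width statistics, sliding-window firing rates, and
sub-frame peak-time maps of propagating events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.interpolate import make_interp_spline
from scipy.ndimage import gaussian_filter, median_filter

from .metrics import FWHM_PER_SIGMA, fwhm_gaussian

__all__ = [
    "Trace",
    "SpikeSet",
    "dff",
    "detect_spikes",
    "spike_stats",
    "firing_rate",
    "peak_time_map",
]


@dataclass
class Trace:
    """ROI-mean fluorescence versus time at sampling rate ``rate_hz``."""

    f: np.ndarray
    rate_hz: float = 500.0
    roi: str = ""

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=np.float64)
        if self.f.ndim != 1:
            raise ValueError("trace must be 1D")
        if not np.all(np.isfinite(self.f)):
            raise ValueError("trace contains non-finite samples")
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")


@dataclass
class SpikeSet:
    """Detected spikes: peak sample indices, times, amplitudes, widths."""

    indices: np.ndarray
    times_s: np.ndarray
    amplitudes: np.ndarray
    threshold: float
    rate_hz: float
    fwhms_ms: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)


def dff(trace: Trace) -> np.ndarray:
    """Delta-F/F0 = (F - F0) / F0 with F0 the mean over the whole series."""
    f0 = float(trace.f.mean())
    if f0 <= 0:
        raise ValueError("baseline F0 must be positive")
    return (trace.f - f0) / f0


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Strict local maxima; plateaus resolve to their first sample."""
    n = len(x)
    idx = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] < x[i]:
                idx.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(idx, dtype=int)


def detect_spikes(dff_series: np.ndarray, threshold: float = 0.02,
                  med_window_ms: float = 40.0,
                  rate_hz: float = 500.0) -> SpikeSet:
    """Detect spikes as local peaks above ``threshold`` on the
    baseline-subtracted trace.

    The slow baseline is a median filter of ``med_window_ms`` (40 ms at the
    paper-scale 500 Hz sampling); detection thresholds of 0.02 (snapshot
    virtual-scanning traces) and 0.012 (hardware-scanned traces) match the
    analysis conventions this module reproduces.  Detection is invariant to
    additive constants because the median baseline absorbs them.
    """
    x = np.asarray(dff_series, dtype=np.float64)
    win = int(round(med_window_ms * 1e-3 * rate_hz))
    win = max(win | 1, 3)  # odd
    if win >= len(x):
        raise ValueError("median window longer than the trace")
    resid = x - median_filter(x, size=win, mode="nearest")
    peaks = _local_maxima(resid)
    peaks = peaks[resid[peaks] >= threshold]
    return SpikeSet(indices=peaks, times_s=peaks / rate_hz,
                    amplitudes=np.abs(resid[peaks]), threshold=threshold,
                    rate_hz=rate_hz)


def spike_stats(dff_series: np.ndarray, spikes: SpikeSet,
                window_ms: float = 40.0):
    """Per-spike FWHM and amplitude plus the peak-aligned average waveform.

    Each spike is windowed around its peak sample; spikes whose window
    leaves the trace are excluded (and reported).  Widths come from a
    Gaussian fit to the windowed waveform; amplitudes are the absolute
    baseline-subtracted peak values recorded at detection.

    Returns a dict with ``fwhms_ms``, ``amplitudes``, ``waveform``,
    ``waveform_t_ms`` and ``excluded`` (count of edge spikes).
    """
    x = np.asarray(dff_series, dtype=np.float64)
    if len(spikes) == 0:
        raise ValueError("spike set is empty")
    half = max(int(round(window_ms * 1e-3 * spikes.rate_hz / 2)), 2)
    waveforms, fwhms, amps = [], [], []
    excluded = 0
    win = x[:0]
    for i, amp in zip(spikes.indices, spikes.amplitudes):
        if i - half < 0 or i + half + 1 > len(x):
            excluded += 1
            continue
        win = x[i - half:i + half + 1]
        waveforms.append(win - win.min())
        amps.append(amp)
        try:
            fwhm_samples = fwhm_gaussian(win - win.min())
        except ValueError:
            fwhm_samples = math.nan
        fwhms.append(fwhm_samples / spikes.rate_hz * 1e3)
    if not waveforms:
        raise ValueError("all spikes fall too close to the trace edges")
    waveform = np.mean(waveforms, axis=0)
    t_ms = (np.arange(-half, half + 1)) / spikes.rate_hz * 1e3
    return {"fwhms_ms": np.asarray(fwhms), "amplitudes": np.asarray(amps),
            "waveform": waveform, "waveform_t_ms": t_ms,
            "excluded": excluded}


def firing_rate(spikes: SpikeSet, duration_s: float,
                window_s: float = 1.0, dt_s: float = 0.01) -> tuple[np.ndarray,
                                                                    np.ndarray]:
    """Sliding-window firing rate (spikes per second, centered windows).

    Returns (time grid, rate curve); an empty spike set yields a zero curve.
    The integral of the curve over time approximates the spike count (up to
    edge effects of the centered window).
    """
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    rate = np.zeros_like(t)
    for i, tc in enumerate(t):
        lo, hi = tc - window_s / 2, tc + window_s / 2
        rate[i] = np.count_nonzero((spikes.times_s >= lo)
                                   & (spikes.times_s < hi)) / window_s
    return t, rate


def peak_time_map(movie: np.ndarray, rate_hz: float = 500.0,
                  spatial_sigma: float = 9.0, rise_fraction: float = 0.5,
                  min_amplitude: float = 0.0, upsample: int = 10,
                  wavelet: str = "sym4") -> np.ndarray:
    """Sub-frame peak-time map of a single spike event.

    Per voxel: apply a spatial Gaussian filter (sigma = 9 voxels at paper
    scale), denoise the time course with a soft-threshold wavelet shrinkage
    (symlet-4 by default), fit a quadratic spline through the samples on an
    ``upsample``-times finer time grid, and report the rising-edge time at
    which the trace first crosses ``rise_fraction`` of its peak amplitude.
    Voxels whose amplitude never reaches ``min_amplitude`` (or that never
    cross) are masked as NaN.

    ``movie`` is (t, z, y, x) or (t, y, x); the returned map drops the time
    axis and holds crossing times in seconds.
    """
    movie = np.asarray(movie, dtype=np.float64)
    if movie.ndim not in (3, 4):
        raise ValueError("movie must be (t, y, x) or (t, z, y, x)")
    nt = movie.shape[0]
    if nt < 5:
        raise ValueError("event window too short")
    smoothed = np.empty_like(movie)
    for it in range(nt):
        smoothed[it] = gaussian_filter(movie[it], sigma=spatial_sigma,
                                       mode="nearest")
    flat = smoothed.reshape(nt, -1)
    t = np.arange(nt) / rate_hz
    t_fine = np.linspace(t[0], t[-1], (nt - 1) * upsample + 1)
    out = np.full(flat.shape[1], np.nan)
    for j in range(flat.shape[1]):
        y = _wavelet_denoise(flat[:, j], wavelet)
        base = y.min()
        amp = y.max() - base
        if amp <= min_amplitude or amp == 0:
            continue
        spline = make_interp_spline(t, y, k=2)
        yf = spline(t_fine)
        peak = int(np.argmax(yf))
        level = base + rise_fraction * amp
        rising = np.flatnonzero(yf[:peak + 1] >= level)
        if rising.size == 0:
            continue
        out[j] = t_fine[rising[0]]
    return out.reshape(movie.shape[1:])


def _wavelet_denoise(y: np.ndarray, wavelet: str) -> np.ndarray:
    """Soft-threshold wavelet shrinkage with the universal threshold."""
    n = len(y)
    level = min(2, pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len))
    if level < 1:
        return y
    coeffs = pywt.wavedec(y, wavelet, level=level, mode="symmetric")
    detail = coeffs[-1]
    sigma = np.median(np.abs(detail - np.median(detail))) / 0.6745
    thresh = sigma * math.sqrt(2 * math.log(max(n, 2)))
    if thresh <= 0:
        return y  # noise-free (e.g. constant) trace: nothing to shrink
    coeffs = [coeffs[0]] + [pywt.threshold(c, thresh, mode="soft")
                            for c in coeffs[1:]]
    out = pywt.waverec(coeffs, wavelet, mode="symmetric")
    return out[:n]
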