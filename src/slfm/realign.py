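"""Pixel realignment between raw macro-pixel frames and spatial-angular views.

A raw light-field frame tiles the sensor into p x p macro-pixels, one per
microlens; sensor pixel (u, v) within a macro-pixel samples pupil angle
(u, v).  Realignment is a pure index permutation: view (u, v) collects that
pixel from every macro-pixel.  For a 3x3 galvo scan the nine snapshot view
sets interleave onto a 3x finer spatial grid.  Every operation here is
lossless and bit-exact; energies are exactly conserved on integer data.

Conventions (configurable upstream, fixed here): 0-based row-major indexing
with origin top-left; angle (0, 0) is the top-left pupil corner so the
chief-ray view sits at the center index ((a-1)/2, (a-1)/2); the frame with
offset (-1/3, -1/3) pitch fills high-resolution sub-phase (0, 0), i.e.
offsets map to sub-phases by a +1 index shift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .lfsim import ScanSeries

__all__ = [
    "RawLightFieldImage",
    "SpatialAngularViews",
    "realign_snapshot",
    "views_to_raw",
    "realign_series",
    "center_frame",
    "crop_to_lattice",
]


@dataclass
class RawLightFieldImage:
    """2D sensor frame tiled into macro-pixels of pitch ``pitch_px``.

    ``origin`` is the (row, col) of the first full macro-pixel; the usable
    region spans ``n_lens_side * pitch_px`` sensor pixels per side.
    """

    data: np.ndarray
    pitch_px: int
    n_lens_side: int
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raw frame must be 2D")
        if self.pitch_px % 2 == 0:
            raise ValueError("microlens pitch must cover an odd pixel count")
        side = self.n_lens_side * self.pitch_px
        r0, c0 = self.origin
        if (r0 < 0 or c0 < 0 or r0 + side > self.data.shape[0]
                or c0 + side > self.data.shape[1]):
            raise ValueError("declared macro-pixel region exceeds the frame")

    @property
    def usable(self) -> np.ndarray:
        side = self.n_lens_side * self.pitch_px
        r0, c0 = self.origin
        return self.data[r0:r0 + side, c0:c0 + side]


@dataclass
class SpatialAngularViews:
    """4D spatial-angular tensor ``data[u][v][y][x]``.

    ``scale`` is 1 for a snapshot realignment and 3 for a scanned (or
    virtually scanned) set whose spatial grid is 3x finer.
    """

    data: np.ndarray
    n_angles_side: int
    scale: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        a = self.n_angles_side
        if self.data.ndim != 4 or self.data.shape[0] != a \
                or self.data.shape[1] != a:
            raise ValueError("views must be (u, v, y, x) with matching "
                             "angle extents")
        if self.scale not in (1, 3):
            raise ValueError("scale must be 1 or 3")
        if np.issubdtype(self.data.dtype, np.floating) \
                and not np.all(np.isfinite(self.data)):
            raise ValueError("views contain non-finite values")

    @property
    def spatial_side(self) -> int:
        return self.data.shape[2]

    @property
    def center_view(self) -> np.ndarray:
        c = (self.n_angles_side - 1) // 2
        return self.data[c, c]


def crop_to_lattice(frame: np.ndarray, pitch_px: int,
                    n_lens: int | None = None) -> RawLightFieldImage:
    """Centrally crop a sensor frame to a whole macro-pixel grid.

    ``n_lens`` defaults to the largest grid the frame can hold; real
    instruments use fewer (a 2,048-square sensor at pitch 13 is operated
    as 153 lenses / 1,989 px, leaving margin for scan shifts and lattice
    alignment), so pass the system's usable lens count explicitly.  The
    crop origin is recorded on the returned image.
    """
    frame = np.asarray(frame)
    n_max = min(frame.shape) // pitch_px
    n_lens = n_max if n_lens is None else n_lens
    if n_lens < 1 or n_lens > n_max:
        raise ValueError("requested lens grid does not fit the frame")
    side = n_lens * pitch_px
    r0 = (frame.shape[0] - side) // 2
    c0 = (frame.shape[1] - side) // 2
    return RawLightFieldImage(frame, pitch_px, n_lens, origin=(r0, c0))


def realign_snapshot(raw: RawLightFieldImage) -> SpatialAngularViews:
    """Rearrange a single raw frame into scale-1 spatial-angular views.

    view[u, v, y, x] = usable[y * p + u, x * p + v]; no interpolation.
    """
    p, n = raw.pitch_px, raw.n_lens_side
    region = raw.usable
    views = (region.reshape(n, p, n, p)   # (y, u, x, v)
             .transpose(1, 3, 0, 2)       # (u, v, y, x)
             .copy())
    return SpatialAngularViews(views, n_angles_side=p, scale=1)


def views_to_raw(views: SpatialAngularViews) -> RawLightFieldImage:
    """Exact inverse of :func:`realign_snapshot` (scale-1 views only)."""
    if views.scale != 1:
        raise ValueError("only scale-1 views pack into a raw frame")
    p = views.n_angles_side
    n = views.spatial_side
    raw = (views.data.transpose(2, 0, 3, 1)   # (y, u, x, v)
           .reshape(n * p, n * p)
           .copy())
    return RawLightFieldImage(raw, pitch_px=p, n_lens_side=n)


def _offset_to_subphase(off: float) -> int:
    sub = round(off * 3) + 1
    if sub not in (0, 1, 2):
        raise ValueError(f"offset {off} is not on the pitch/3 scan grid")
    return sub


def realign_series(series: "ScanSeries") -> SpatialAngularViews:
    """Interleave the 9 snapshot realignments onto a 3x finer grid.

    The frame with pitch offset (dy, dx) fills high-resolution sub-phase
    (3*dy + 1, 3*dx + 1); a complete series covers all nine sub-phases
    exactly once, so total energy is conserved exactly on integer data.
    """
    seen = set()
    parts = {}
    for frame, (dy, dx) in zip(series.frames, series.offsets):
        key = (_offset_to_subphase(dy), _offset_to_subphase(dx))
        if key in seen:
            raise ValueError(f"duplicate scan offset for sub-phase {key}")
        seen.add(key)
        parts[key] = realign_snapshot(frame)
    if len(seen) != 9:
        raise ValueError("scan series does not cover all nine sub-phases")
    any_view = next(iter(parts.values()))
    a = any_view.n_angles_side
    n = any_view.spatial_side
    hr = np.empty((a, a, 3 * n, 3 * n), dtype=any_view.data.dtype)
    for (py, px), v in parts.items():
        hr[:, :, py::3, px::3] = v.data
    return SpatialAngularViews(hr, n_angles_side=a, scale=3)


def center_frame(series: "ScanSeries") -> RawLightFieldImage:
    """Return the zero-offset ("middle") frame of a scan series.

    Looked up by offset, not by position, so shuffled series still resolve;
    in canonical row-major order this is index 4.
    """
    for frame, (dy, dx) in zip(series.frames, series.offsets):
        if round(dy * 3) == 0 and round(dx * 3) == 0:
            return frame
    raise ValueError("series has no zero-offset frame")
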