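"""Fluorescence signals and local contraction measures.

From the stabilized movie, region-of-interest traces F(t), dF = F - F0
and dF/F0 report calcium-indicator activity.  From the displacement
field, an initially uniform grid of squares (default 10 x 10 um, so
K0 = 100 um^2) is advected with the tissue; the shoelace area K(t) of
each deformed quadrilateral gives the local area contraction
dK = K0 - K and the fractional contraction dK/K0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import polygon2mask

from .correction import CorrectedStack
from .field import DisplacementField


@dataclass
class ROISignal:
    """Mean-intensity trace of one region of interest.

    ``F`` is the per-frame mean over unmasked ROI pixels (NaN where the
    ROI is fully masked); ``F0`` the baseline; ``dF = F - F0`` and
    ``dFF0 = (F - F0)/F0``.
    """

    roi_id: int
    F: np.ndarray
    F0: float
    times_s: np.ndarray

    @property
    def dF(self) -> np.ndarray:
        return self.F - self.F0

    @property
    def dFF0(self) -> np.ndarray:
        return (self.F - self.F0) / self.F0


def _roi_mask(roi, shape: tuple[int, int]) -> np.ndarray:
    roi = np.asarray(roi)
    if roi.dtype == bool:
        if roi.shape != shape:
            raise ValueError("ROI mask shape does not match the frames")
        return roi
    # polygon given as (row, col) vertices
    return polygon2mask(shape, roi.astype(float))


def roi_signal(corrected: CorrectedStack,
               roi,
               baseline_method: str = "lowest_decile",
               baseline_window: tuple[int, int] | None = None,
               roi_id: int = 0) -> ROISignal:
    """Mean ROI intensity over time with a baseline estimate.

    ``roi`` is a boolean mask or an array of (row, col) polygon
    vertices.  Only pixels valid in the correction mask enter the mean.
    Baselines: ``lowest_decile`` (default, mean of the lowest 10% of
    F(t) -- robust when transients dominate the trace), ``first_frame``,
    or ``window`` using ``baseline_window = (lo, hi)`` frame indices of
    a quiescent period.
    """
    mask = _roi_mask(roi, corrected.shape)
    if not mask.any():
        raise ValueError("empty ROI")
    n = corrected.n_frames
    F = np.empty(n)
    for t in range(n):
        ok = mask & corrected.mask[t]
        F[t] = corrected.frames[t][ok].mean() if ok.any() else np.nan

    finite = F[np.isfinite(F)]
    if finite.size == 0:
        raise ValueError("ROI fully masked in every frame")
    if baseline_method == "lowest_decile":
        k = max(1, int(np.ceil(0.1 * finite.size)))
        F0 = float(np.sort(finite)[:k].mean())
    elif baseline_method == "first_frame":
        F0 = float(F[0])
    elif baseline_method == "window":
        if baseline_window is None:
            raise ValueError("baseline_window required for method 'window'")
        lo, hi = baseline_window
        F0 = float(np.nanmean(F[lo:hi]))
    else:
        raise ValueError(f"unknown baseline method {baseline_method!r}")
    times = np.arange(n) * corrected.frame_interval_s
    return ROISignal(roi_id, F, F0, times)


def quad_area(vertices: np.ndarray) -> tuple[float, bool]:
    """Shoelace area (absolute) of an ordered quadrilateral.

    Returns ``(area, degenerate)`` where ``degenerate`` marks a
    self-intersecting (bow-tie) vertex ordering, detected by opposite
    edges crossing; the shoelace value is still returned.
    """
    v = np.asarray(vertices, dtype=float)
    if v.shape != (4, 2):
        raise ValueError("expected 4 ordered (row, col) vertices")
    x, y = v[:, 0], v[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)

    def crosses(p1, p2, p3, p4):
        def orient(a, b, c):
            return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return (orient(p1, p2, p3) * orient(p1, p2, p4) < 0
                and orient(p3, p4, p1) * orient(p3, p4, p2) < 0)

    degenerate = (crosses(v[0], v[1], v[2], v[3])
                  or crosses(v[1], v[2], v[3], v[0]))
    return float(abs(signed)), bool(degenerate)


def _signed_cell_areas(vertices: np.ndarray) -> np.ndarray:
    """Signed shoelace areas of all grid cells, vectorised.

    ``vertices`` is (Gr, Gc, 2); cells are the quadrilaterals between
    adjacent vertices, traversed counter-clockwise in (row, col) index
    order.
    """
    v00 = vertices[:-1, :-1]
    v01 = vertices[:-1, 1:]
    v11 = vertices[1:, 1:]
    v10 = vertices[1:, :-1]
    quad = np.stack([v00, v01, v11, v10], axis=2)  # (gr, gc, 4, 2)
    x = quad[..., 0]
    y = quad[..., 1]
    return 0.5 * np.sum(x * np.roll(y, -1, axis=2)
                        - np.roll(x, -1, axis=2) * y, axis=2)


@dataclass
class ContractionGrid:
    """Warped quadrilateral mesh with per-cell area history.

    ``vertices`` is (n_frames, Gr, Gc, 2) in pixels; ``K`` the per-cell
    areas in um^2, (n_frames, Gr-1, Gc-1); ``K0`` the frame-1 area of
    every cell.  ``dK = K0 - K`` and ``dK_over_K0 = dK/K0`` are positive
    where tissue has contracted.
    """

    vertices: np.ndarray
    K: np.ndarray
    K0: float
    spacing_um: float
    times_s: np.ndarray
    degenerate: np.ndarray    # bool, (n_frames, Gr-1, Gc-1)

    @property
    def dK(self) -> np.ndarray:
        return self.K0 - self.K

    @property
    def dK_over_K0(self) -> np.ndarray:
        return self.dK / self.K0

    def cell_trace(self, row: int, col: int) -> np.ndarray:
        """dK/K0 time series of one grid cell."""
        return self.dK_over_K0[:, row, col]


def contraction_field(field: DisplacementField,
                      spacing_um: float = 10.0) -> ContractionGrid:
    """Advect a uniform square grid with the field and measure cell areas.

    The grid spacing must be at least 2 px.  Vertex displacements are
    bilinear samples of the dense field, so the mesh moves with the same
    kernel-based motion as the pixels.  Cells whose vertex ordering
    self-intersects in a frame are flagged degenerate (area still
    computed).
    """
    px = field.pixel_width_um
    spacing_px = spacing_um / px
    if spacing_px < 2:
        raise ValueError("grid spacing must be at least 2 pixels")
    H, W = field.shape
    rows = np.arange(0, H - 1e-9, spacing_px)
    cols = np.arange(0, W - 1e-9, spacing_px)
    if len(rows) < 2 or len(cols) < 2:
        raise ValueError("frame too small for the requested grid spacing")
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    n = field.n_frames

    vertices = np.empty((n, len(rows), len(cols), 2))
    for t in range(n):
        dr = ndimage.map_coordinates(field.D_p[t, :, :, 0], [rr, cc],
                                     order=1, mode="nearest")
        dc = ndimage.map_coordinates(field.D_p[t, :, :, 1], [rr, cc],
                                     order=1, mode="nearest")
        vertices[t, :, :, 0] = rr + dr
        vertices[t, :, :, 1] = cc + dc

    signed = np.stack([_signed_cell_areas(vertices[t]) for t in range(n)])
    K = np.abs(signed) * px**2
    K0 = float(spacing_px**2 * px**2)
    # sign flip relative to frame 1 indicates a folded (bow-tie) cell
    degenerate = np.sign(signed) != np.sign(signed[0])
    times = np.arange(n) * field.frame_interval_s
    return ContractionGrid(vertices, K, K0, spacing_um, times, degenerate)


class Timing(NamedTuple):
    """Rise and fall times between two fractional levels of the peak."""

    rise_s: float
    fall_s: float


def _interp_crossing(times: np.ndarray, trace: np.ndarray,
                     level: float, start: int, stop: int, step: int,
                     upward: bool) -> float:
    """Time at which the trace crosses ``level``, scanning start->stop."""
    idx = range(start, stop, step)
    for i in idx:
        j = i + step
        a, b = trace[i], trace[j]
        crossed = (a < level <= b) if upward else (a > level >= b)
        if crossed and a != b:
            frac = (level - a) / (b - a)
            return float(times[i] + frac * (times[j] - times[i]))
        if crossed:
            return float(times[j])
    return np.nan


def signal_timing(trace: np.ndarray,
                  times_s: np.ndarray,
                  lo_frac: float = 0.2,
                  hi_frac: float = 0.8) -> Timing:
    """20-80%-style rise and fall times of a transient.

    The peak is the trace maximum; levels are ``lo_frac`` and
    ``hi_frac`` of the peak value (the trace baseline is assumed near
    zero, as for dF/F0 or dK/K0).  Rise time is measured between the
    last upward lo-crossing before the peak and the following
    hi-crossing; fall time between the first downward hi- and
    lo-crossings after the peak, with linear interpolation between
    samples.  NaN is returned for phases that never cross the levels.
    """
    trace = np.asarray(trace, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if np.all(~np.isfinite(trace)) or np.nanmax(trace) <= 0:
        return Timing(np.nan, np.nan)
    peak_idx = int(np.nanargmax(trace))
    peak = trace[peak_idx]
    lo, hi = lo_frac * peak, hi_frac * peak

    # rising phase: scan backwards from the peak for the crossings
    t_hi_rise = _interp_crossing(times_s, trace, hi, 0, peak_idx, 1, True)
    t_lo_rise = np.nan
    for i in range(peak_idx - 1, -1, -1):
        if trace[i] < lo <= trace[i + 1]:
            frac = (lo - trace[i]) / (trace[i + 1] - trace[i])
            t_lo_rise = float(times_s[i] + frac * (times_s[i + 1] - times_s[i]))
            break
    rise = t_hi_rise - t_lo_rise if np.isfinite(t_hi_rise + t_lo_rise) else np.nan

    t_hi_fall = _interp_crossing(times_s, trace, hi, peak_idx,
                                 len(trace) - 1, 1, False)
    t_lo_fall = _interp_crossing(times_s, trace, lo, peak_idx,
                                 len(trace) - 1, 1, False)
    fall = t_lo_fall - t_hi_fall if np.isfinite(t_hi_fall + t_lo_fall) else np.nan
    return Timing(rise, fall)
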