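"""Dense displacement-field extrapolation and the characteristic length scale.

Landmark displacements-from-frame-1 are extrapolated to every pixel with
a distance-weighted average,

    D_p(lambda) = sum_l w(phi_pl; lambda) D_l / sum_l w(phi_pl; lambda),

where phi_pl is the frame-1 distance between pixel p and landmark l and
the weighting kernel is Gaussian, w(phi; lambda) = exp(-phi^2/lambda^2).
The length scale lambda_c -- the scale below which tissue motion is
locally homogeneous -- is found by leave-one-out prediction of the known
landmark displacements over a grid of lambda values.  In the limits,
lambda -> 0 gives the nearest-landmark (Voronoi) field and
lambda -> infinity the unweighted mean field.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .tracking import Trajectory

log = logging.getLogger(__name__)

Kernel = Callable[[np.ndarray, float], np.ndarray]


def gaussian_kernel(phi: np.ndarray, lam: float) -> np.ndarray:
    """w(phi; lambda) = exp(-phi^2 / lambda^2); handles the 0/inf limits.

    lambda = 0 yields an indicator of phi == 0 (nearest-landmark
    behaviour is implemented by the callers via explicit argmin);
    lambda = inf yields uniform weights.
    """
    phi = np.asarray(phi, dtype=float)
    if np.isinf(lam):
        return np.ones_like(phi)
    if lam == 0:
        return (phi == 0).astype(float)
    return np.exp(-(phi / lam) ** 2)


def exponential_kernel(phi: np.ndarray, lam: float) -> np.ndarray:
    """Alternative kernel w(phi; lambda) = exp(-phi / lambda)."""
    phi = np.asarray(phi, dtype=float)
    if np.isinf(lam):
        return np.ones_like(phi)
    if lam == 0:
        return (phi == 0).astype(float)
    return np.exp(-phi / lam)


@dataclass
class DisplacementField:
    """Per-pixel displacement from frame 1, for every frame.

    ``D_p`` has shape ``(n_frames, height, width, 2)`` in pixels, (row,
    col) components; frame 1 is identically zero.  ``error_curve`` is
    the leave-one-out error per grid lambda (um) and ``lambda_c`` its
    (refined) minimiser.
    """

    D_p: np.ndarray
    lambda_used: float                 # um
    pixel_width_um: float
    frame_interval_s: float
    error_curve: np.ndarray | None = None   # columns: lambda_um, err_um, normalized
    lambda_c: float | None = None

    @property
    def n_frames(self) -> int:
        return self.D_p.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.D_p.shape[1:3]

    def positions(self) -> np.ndarray:
        """Per-pixel tissue position (frame, row, col, 2), initial + D_p."""
        rows, cols = np.mgrid[0:self.shape[0], 0:self.shape[1]].astype(float)
        base = np.stack([rows, cols], axis=-1)
        return base[None] + self.D_p

    def velocity(self) -> np.ndarray:
        """Per-pixel velocity (px/s) by central differences in time."""
        return np.gradient(self.D_p, self.frame_interval_s, axis=0)

    def acceleration(self) -> np.ndarray:
        """Per-pixel acceleration (px/s^2)."""
        return np.gradient(self.velocity(), self.frame_interval_s, axis=0)


def landmark_displacements(trajectories: Sequence[Trajectory]
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frame-1 positions, displacements and validity from trajectories.

    Returns ``pos0`` (L, 2) px, ``disp`` (L, N, 2) px with NaN replaced
    by 0, and a boolean validity mask (L, N); a landmark contributes
    only in frames where it was tracked.
    """
    pos0 = np.stack([t.positions[0] for t in trajectories])
    disp = np.stack([t.displacements() for t in trajectories])
    valid = np.all(np.isfinite(disp), axis=-1)
    return pos0, np.nan_to_num(disp), valid


def _weights(points_px: np.ndarray, pos0_px: np.ndarray,
             lam_um: float, pixel_width_um: float,
             kernel: Kernel) -> np.ndarray:
    """Kernel weights, shape (n_points, n_landmarks)."""
    phi_px = np.sqrt(np.sum(
        (points_px[:, None, :] - pos0_px[None, :, :]) ** 2, axis=-1))
    return kernel(phi_px * pixel_width_um, lam_um)


def _weighted_average(weights: np.ndarray, disp: np.ndarray,
                      valid: np.ndarray, points_px: np.ndarray,
                      pos0_px: np.ndarray) -> np.ndarray:
    """Weighted average of displacements, (n_points, n_frames, 2).

    Points where every weight underflows to zero (or no landmark is
    valid) fall back to the nearest valid landmark's displacement.
    """
    n_points = weights.shape[0]
    L, N, _ = disp.shape
    wv = weights[:, :, None] * valid[None, :, :]          # (P, L, N)
    den = wv.sum(axis=1)                                  # (P, N)
    num = np.einsum("pln,lnc->pnc", wv, disp)             # (P, N, 2)
    out = np.empty((n_points, N, 2))
    ok = den > 0
    out[ok] = num[ok] / den[ok][:, None]
    if not np.all(ok):
        warnings.warn("all kernel weights zero for some pixels; "
                      "falling back to nearest landmark", stacklevel=2)
        dist = np.sqrt(np.sum(
            (points_px[:, None, :] - pos0_px[None, :, :]) ** 2, axis=-1))
        for p, t in zip(*np.nonzero(~ok)):
            d = np.where(valid[:, t], dist[p], np.inf)
            out[p, t] = disp[int(np.argmin(d)), t]
    return out


def weighted_displacement(point_px: Sequence[float],
                          pos0_px: np.ndarray,
                          disp_px: np.ndarray,
                          lam_um: float,
                          pixel_width_um: float = 1.0,
                          frame: int | None = None,
                          valid: np.ndarray | None = None,
                          kernel: Kernel = gaussian_kernel) -> np.ndarray:
    """Distance-weighted displacement estimate at one point.

    ``disp_px`` is (L, n_frames, 2); returns (n_frames, 2), or (2,) when
    ``frame`` is given.  ``lam_um = 0`` gives the nearest valid
    landmark's displacement, ``lam_um = inf`` the unweighted mean.
    """
    point = np.asarray(point_px, dtype=float)[None, :]
    pos0_px = np.asarray(pos0_px, dtype=float)
    disp_px = np.asarray(disp_px, dtype=float)
    if valid is None:
        valid = np.ones(disp_px.shape[:2], dtype=bool)
    if lam_um == 0:
        dist = np.sqrt(np.sum((pos0_px - point) ** 2, axis=-1))
        out = np.empty((disp_px.shape[1], 2))
        for t in range(disp_px.shape[1]):
            d = np.where(valid[:, t], dist, np.inf)
            out[t] = disp_px[int(np.argmin(d)), t]
    else:
        w = _weights(point, pos0_px, lam_um, pixel_width_um, kernel)
        out = _weighted_average(w, disp_px, valid, point, pos0_px)[0]
    return out if frame is None else out[frame]


@dataclass
class LambdaResult:
    """Leave-one-out error curve and its minimiser."""

    lambda_grid: np.ndarray        # um
    mean_error_um: np.ndarray
    normalized_error: np.ndarray   # scaled to max 1 (for reporting)
    lambda_c: float                # um, parabolically refined
    at_boundary: bool

    def as_table(self) -> np.ndarray:
        return np.column_stack([self.lambda_grid, self.mean_error_um,
                                self.normalized_error])


def optimize_lambda(pos0_px: np.ndarray,
                    disp_px: np.ndarray,
                    lambda_grid_um: np.ndarray,
                    pixel_width_um: float = 1.0,
                    valid: np.ndarray | None = None,
                    kernel: Kernel = gaussian_kernel) -> LambdaResult:
    """Find the characteristic length scale by leave-one-out prediction.

    For each lambda on the grid, every landmark's displacement is
    predicted as the weighted average over all *other* landmarks; the
    error is the mean Euclidean prediction error over landmarks and
    valid frames.  The grid argmin is refined by parabolic interpolation
    in log-lambda over the three bracketing points; a minimum on the
    grid edge is reported as-is with ``at_boundary`` set.
    """
    pos0_px = np.asarray(pos0_px, dtype=float)
    disp_px = np.asarray(disp_px, dtype=float)
    grid = np.asarray(lambda_grid_um, dtype=float)
    L = len(pos0_px)
    if L < 2:
        raise ValueError("need at least 2 landmarks to optimize lambda")
    if valid is None:
        valid = np.ones(disp_px.shape[:2], dtype=bool)

    phi_um = np.sqrt(np.sum(
        (pos0_px[:, None, :] - pos0_px[None, :, :]) ** 2,
        axis=-1)) * pixel_width_um

    errors = np.empty(len(grid))
    for gi, lam in enumerate(grid):
        w = kernel(phi_um, lam)
        np.fill_diagonal(w, 0.0)                         # leave one out
        wv = w[:, :, None] * valid[None, :, :]           # (L, L, N)
        den = wv.sum(axis=1)                             # (L, N)
        num = np.einsum("pln,lnc->pnc", wv, disp_px)     # (L, N, 2)
        pred = np.full_like(num, np.nan)
        ok = den > 0
        pred[ok] = num[ok] / den[ok][:, None]
        err = np.linalg.norm(pred - disp_px, axis=-1)    # (L, N)
        use = valid & ok
        errors[gi] = np.mean(err[use]) * pixel_width_um

    idx = int(np.argmin(errors))
    at_boundary = idx in (0, len(grid) - 1)
    if at_boundary:
        warnings.warn("lambda error curve minimal at grid edge; "
                      "lambda_c may be outside the grid", stacklevel=2)
        lambda_c = float(grid[idx])
    else:
        # parabola through the three bracketing points in log-lambda
        x = np.log(grid[idx - 1:idx + 2])
        y = errors[idx - 1:idx + 2]
        denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
        a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2])
             + x[0] * (y[2] - y[1])) / denom
        b = (x[2]**2 * (y[0] - y[1]) + x[1]**2 * (y[2] - y[0])
             + x[0]**2 * (y[1] - y[2])) / denom
        lambda_c = float(np.exp(-b / (2 * a))) if a > 0 else float(grid[idx])

    norm = errors / errors.max() if errors.max() > 0 else errors
    return LambdaResult(grid, errors, norm, lambda_c, at_boundary)


def build_field(pos0_px: np.ndarray,
                disp_px: np.ndarray,
                lambda_um: float,
                frame_shape: tuple[int, int],
                pixel_width_um: float = 1.0,
                frame_interval_s: float = 1.0,
                valid: np.ndarray | None = None,
                kernel: Kernel = gaussian_kernel,
                error_curve: np.ndarray | None = None,
                lambda_c: float | None = None,
                row_chunk: int = 16) -> DisplacementField:
    """Evaluate the weighted displacement at every pixel of every frame."""
    if not lambda_um > 0:
        raise ValueError("lambda must be positive")
    pos0_px = np.asarray(pos0_px, dtype=float)
    disp_px = np.asarray(disp_px, dtype=float)
    if valid is None:
        valid = np.ones(disp_px.shape[:2], dtype=bool)
    H, W = frame_shape
    N = disp_px.shape[1]
    D_p = np.empty((N, H, W, 2))
    cols = np.arange(W, dtype=float)
    for r0 in range(0, H, row_chunk):
        r1 = min(r0 + row_chunk, H)
        rows, cc = np.meshgrid(np.arange(r0, r1, dtype=float), cols,
                               indexing="ij")
        pts = np.column_stack([rows.ravel(), cc.ravel()])
        w = _weights(pts, pos0_px, lambda_um, pixel_width_um, kernel)
        block = _weighted_average(w, disp_px, valid, pts, pos0_px)
        D_p[:, r0:r1] = block.reshape(r1 - r0, W, N, 2).transpose(2, 0, 1, 3)
    return DisplacementField(D_p, lambda_um, pixel_width_um,
                             frame_interval_s, error_curve, lambda_c)


def field_from_trajectories(trajectories: Sequence[Trajectory],
                            frame_shape: tuple[int, int],
                            lambda_grid_um: np.ndarray,
                            pixel_width_um: float,
                            frame_interval_s: float,
                            kernel: Kernel = gaussian_kernel
                            ) -> DisplacementField:
    """Optimize lambda on the trajectories, then build the dense field."""
    pos0, disp, valid = landmark_displacements(trajectories)
    res = optimize_lambda(pos0, disp, lambda_grid_um, pixel_width_um,
                          valid=valid, kernel=kernel)
    log.info("lambda_c = %.2f um (boundary=%s)", res.lambda_c, res.at_boundary)
    return build_field(pos0, disp, res.lambda_c, frame_shape,
                       pixel_width_um, frame_interval_s, valid=valid,
                       kernel=kernel, error_curve=res.as_table(),
                       lambda_c=res.lambda_c)
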