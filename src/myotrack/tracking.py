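"""Frame-to-frame landmark tracking by sub-pixel 2-D Gaussian fitting.

A landmark is followed by re-fitting an isotropic 2-D Gaussian plus
offset,

    I(row, col) = A + B exp(-((row - r0)^2 + (col - c0)^2) / (2 sigma^2)),

to the pixel data inside its (2r+1) x (2r+1) window in each new frame.
Because all five parameters (A, B, sigma and the centre) are free, a
global rescaling of the frame intensities is absorbed by A and B and the
fitted centre is unchanged -- the property that makes the tracker robust
to calcium-transient intensity changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

if TYPE_CHECKING:  # pragma: no cover
    from .detection import Landmark
    from .stack import ImageStack

# Trajectory invalidated after this many consecutive failed fits
# (tolerates transient dimming during calcium troughs).
MAX_CONSECUTIVE_MISSES = 3


class GaussianFit(NamedTuple):
    """Result of a single window fit; centre in window coordinates."""

    A: float
    B: float
    sigma: float
    row: float
    col: float
    residual: float      # RMS of (model - data)
    converged: bool


@dataclass
class Trajectory:
    """Per-frame sub-pixel positions of one tracked landmark.

    ``positions`` has shape ``(n_frames, 2)`` in image (row, col) pixel
    coordinates; entries after ``exit_frame`` are NaN when tracking
    terminated early.  ``fit_params`` holds (A, B, sigma) per frame.
    """

    landmark_id: int
    positions: np.ndarray
    fit_params: np.ndarray
    residuals: np.ndarray
    valid: bool = True
    exit_frame: int | None = None

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def displacements(self) -> np.ndarray:
        """Displacement from the frame-1 position, shape (n_frames, 2)."""
        return self.positions - self.positions[0]


def _residual_and_jac(params, rows, cols, data):
    A, B, sigma, r0, c0 = params
    dr = rows - r0
    dc = cols - c0
    d2 = dr * dr + dc * dc
    E = np.exp(-d2 / (2.0 * sigma * sigma))
    res = A + B * E - data
    J = np.empty((data.size, 5))
    J[:, 0] = 1.0
    J[:, 1] = E
    J[:, 2] = B * E * d2 / sigma**3
    J[:, 3] = B * E * dr / sigma**2
    J[:, 4] = B * E * dc / sigma**2
    return res, J


def fit_gaussian(window_data: np.ndarray,
                 init: Sequence[float]) -> GaussianFit:
    """Least-squares fit of the Gaussian-plus-offset model to one window.

    Parameters
    ----------
    window_data
        Square window of pixel intensities, ``(2r+1) x (2r+1)``.
    init
        Starting values ``(A, B, sigma, row, col)`` with the centre in
        window coordinates (0 .. 2r, pixel-centre convention).

    The centre is constrained to the window interior and sigma to
    ``(0.5, 2r+1)``.  Degenerate input (zero variance) and optimizer
    failure are reported via ``converged=False``; the caller decides
    disposal.
    """
    window_data = np.asarray(window_data, dtype=float)
    size = window_data.shape[0]
    if window_data.shape != (size, size):
        raise ValueError("window must be square")
    if np.ptp(window_data) == 0:
        A0, B0, s0, r0, c0 = init
        return GaussianFit(A0, B0, s0, r0, c0, 0.0, converged=False)

    rows, cols = np.mgrid[0:size, 0:size]
    rows = rows.ravel().astype(float)
    cols = cols.ravel().astype(float)
    data = window_data.ravel()

    A0, B0, s0, r0, c0 = (float(v) for v in init)
    s0 = float(np.clip(s0, 0.51, size - 1e-3))
    r0 = float(np.clip(r0, 0.0, size - 1.0))
    c0 = float(np.clip(c0, 0.0, size - 1.0))
    if B0 <= 0:
        B0 = max(np.ptp(data), 1e-12)

    lower = [-np.inf, 0.0, 0.5, 0.0, 0.0]
    upper = [np.inf, np.inf, float(size), size - 1.0, size - 1.0]
    try:
        result = least_squares(
            lambda p: _residual_and_jac(p, rows, cols, data)[0],
            x0=[A0, B0, s0, r0, c0],
            jac=lambda p: _residual_and_jac(p, rows, cols, data)[1],
            bounds=(lower, upper),
            xtol=1e-10, ftol=1e-10, gtol=1e-10,
            max_nfev=200,
        )
    except Exception:
        return GaussianFit(A0, B0, s0, r0, c0, np.inf, converged=False)

    A, B, sigma, r_fit, c_fit = result.x
    rms = float(np.sqrt(np.mean(result.fun**2)))
    return GaussianFit(float(A), float(B), float(sigma),
                       float(r_fit), float(c_fit), rms,
                       converged=bool(result.success))


def _window_in_bounds(origin: tuple[int, int], size: int,
                      shape: tuple[int, int]) -> bool:
    r, c = origin
    return r >= 0 and c >= 0 and r + size <= shape[0] and c + size <= shape[1]


def track_all(stack: "ImageStack",
              landmarks: Sequence["Landmark"]) -> list[Trajectory]:
    """Track every landmark from frame 1 through the whole stack.

    For frames 2..N the fit is initialised from the previous frame's
    parameters, and the integer window is re-centred on the rounded
    fitted centre whenever the centre drifts more than 0.5 px from the
    window centre.  A trajectory whose window would overhang the image
    border is truncated and marked invalid from that frame, as is one
    whose fit fails to converge in ``MAX_CONSECUTIVE_MISSES``
    consecutive frames.

    Per-landmark failures are recorded on the trajectory, never raised.
    """
    frames = stack.frames
    n_frames, height, width = frames.shape
    out: list[Trajectory] = []

    for lm in landmarks:
        size = 2 * lm.r + 1
        origin = tuple(int(v) for v in lm.window_origin)
        positions = np.full((n_frames, 2), np.nan)
        params = np.full((n_frames, 3), np.nan)
        residuals = np.full(n_frames, np.nan)

        positions[0] = lm.centre0
        params[0] = (lm.fit_A, lm.fit_B, lm.fit_sigma)
        residuals[0] = lm.fit_residual
        prev = GaussianFit(lm.fit_A, lm.fit_B, lm.fit_sigma,
                           lm.centre0[0] - origin[0], lm.centre0[1] - origin[1],
                           lm.fit_residual, True)
        valid = True
        exit_frame: int | None = None
        misses = 0

        for t in range(1, n_frames):
            window = frames[t, origin[0]:origin[0] + size,
                            origin[1]:origin[1] + size]
            fit = fit_gaussian(window, (prev.A, prev.B, prev.sigma,
                                        prev.row, prev.col))
            if not fit.converged:
                misses += 1
                positions[t] = positions[t - 1]
                params[t] = params[t - 1]
                residuals[t] = fit.residual
                if misses >= MAX_CONSECUTIVE_MISSES:
                    valid = False
                    exit_frame = t
                    positions[t - misses + 1:] = np.nan
                    break
                continue
            misses = 0
            abs_row = origin[0] + fit.row
            abs_col = origin[1] + fit.col
            positions[t] = (abs_row, abs_col)
            params[t] = (fit.A, fit.B, fit.sigma)
            residuals[t] = fit.residual
            prev = fit

            # re-centre the window when the blob drifts off-centre
            centre_r = origin[0] + lm.r
            centre_c = origin[1] + lm.r
            if max(abs(abs_row - centre_r), abs(abs_col - centre_c)) > 0.5:
                new_origin = (int(round(abs_row)) - lm.r,
                              int(round(abs_col)) - lm.r)
                if not _window_in_bounds(new_origin, size, (height, width)):
                    valid = False
                    exit_frame = t
                    positions[t + 1:] = np.nan
                    break
                origin = new_origin
                prev = prev._replace(row=abs_row - origin[0],
                                     col=abs_col - origin[1])

        out.append(Trajectory(lm.id, positions, params, residuals,
                              valid=valid, exit_frame=exit_frame))
    return out
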