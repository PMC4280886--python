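"""Motion-corrected (stabilized) image sequences.

Backward (pull) warping from the frame-1 reference grid: the corrected
intensity at pixel p in frame t is the bilinear sample of frame t at
p + D_p(t), i.e. the intensity of the tissue that started under p is
mapped back to its point of origin.  Samples whose source position
leaves the field of view are masked and zero-filled, never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .field import DisplacementField
from .stack import ImageStack
from .tracking import fit_gaussian

# Border pixels of a near-zero field carry displacements at numerical-noise
# level; without a tolerance their bounds test flips on the sign of that
# noise and valid pixels get masked.
_BOUNDS_EPS = 1e-6


@dataclass
class CorrectedStack:
    """Stabilized movie plus per-pixel validity mask.

    ``frames`` matches the input stack's shape and calibration; frame 1
    equals the input's frame 1 exactly.  ``mask`` is True where the
    sampled source position was inside the field of view; masked pixels
    carry 0.
    """

    frames: np.ndarray
    mask: np.ndarray
    pixel_width_um: float
    frame_interval_s: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def as_stack(self) -> ImageStack:
        return ImageStack(self.frames, self.pixel_width_um,
                          self.frame_interval_s)


def correct_stack(stack: ImageStack, field: DisplacementField) -> CorrectedStack:
    """Resample every frame at p + D_p(t) (bilinear), masking out-of-bounds."""
    if field.D_p.shape[:3] != stack.frames.shape:
        raise ValueError(
            f"field shape {field.D_p.shape[:3]} does not match "
            f"stack shape {stack.frames.shape}")
    n, H, W = stack.frames.shape
    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    out = np.empty_like(stack.frames)
    mask = np.empty((n, H, W), dtype=bool)
    out[0] = stack.frames[0]
    mask[0] = True
    for t in range(1, n):
        src_r = rows + field.D_p[t, :, :, 0]
        src_c = cols + field.D_p[t, :, :, 1]
        inside = ((src_r >= -_BOUNDS_EPS) & (src_r <= H - 1 + _BOUNDS_EPS)
                  & (src_c >= -_BOUNDS_EPS) & (src_c <= W - 1 + _BOUNDS_EPS))
        sampled = ndimage.map_coordinates(
            stack.frames[t], [src_r, src_c], order=1, mode="nearest")
        out[t] = np.where(inside, sampled, 0.0)
        mask[t] = inside
    return CorrectedStack(out, mask, stack.pixel_width_um,
                          stack.frame_interval_s)


def _track_feature(frames: np.ndarray, start: tuple[float, float],
                   r: int) -> np.ndarray:
    """Follow one bright feature through a movie by windowed Gaussian fits.

    Returns positions (n_frames, 2); raises if the feature's window
    leaves the image or the initial fit fails.
    """
    n, H, W = frames.shape
    size = 2 * r + 1
    origin = (int(round(start[0])) - r, int(round(start[1])) - r)

    def in_bounds(o):
        return (o[0] >= 0 and o[1] >= 0
                and o[0] + size <= H and o[1] + size <= W)

    if not in_bounds(origin):
        raise ValueError("feature window outside the image")
    window = frames[0, origin[0]:origin[0] + size, origin[1]:origin[1] + size]
    fit = fit_gaussian(window, (float(window.min()), float(np.ptp(window)),
                                size / 3.0, start[0] - origin[0],
                                start[1] - origin[1]))
    if not fit.converged:
        raise ValueError("feature not trackable at the given position")
    positions = np.empty((n, 2))
    positions[0] = (origin[0] + fit.row, origin[1] + fit.col)
    prev = fit
    for t in range(1, n):
        window = frames[t, origin[0]:origin[0] + size,
                        origin[1]:origin[1] + size]
        fit = fit_gaussian(window, (prev.A, prev.B, prev.sigma,
                                    prev.row, prev.col))
        if not fit.converged:
            raise ValueError(f"feature lost at frame {t}")
        abs_pos = (origin[0] + fit.row, origin[1] + fit.col)
        positions[t] = abs_pos
        prev = fit
        centre = (origin[0] + r, origin[1] + r)
        if max(abs(abs_pos[0] - centre[0]), abs(abs_pos[1] - centre[1])) > 0.5:
            new_origin = (int(round(abs_pos[0])) - r,
                          int(round(abs_pos[1])) - r)
            if not in_bounds(new_origin):
                raise ValueError(f"feature left the image at frame {t}")
            origin = new_origin
            prev = prev._replace(row=abs_pos[0] - origin[0],
                                 col=abs_pos[1] - origin[1])
    return positions


def stabilization_metrics(raw: ImageStack,
                          corrected: CorrectedStack,
                          feature: tuple[float, float],
                          r: int = 3) -> dict[str, float]:
    """Peak-to-peak displacement of one feature, before and after correction.

    The feature near ``feature`` (row, col) is tracked through both the
    raw and the corrected movie with the same sub-pixel Gaussian-fit
    tracker; reported are the peak-to-peak vertical (row) and horizontal
    (col) excursions of its centre, in pixels.
    """
    raw_pos = _track_feature(raw.frames, feature, r)
    cor_pos = _track_feature(corrected.frames, feature, r)
    return {
        "raw_ptp_row": float(np.ptp(raw_pos[:, 0])),
        "raw_ptp_col": float(np.ptp(raw_pos[:, 1])),
        "corrected_ptp_row": float(np.ptp(cor_pos[:, 0])),
        "corrected_ptp_col": float(np.ptp(cor_pos[:, 1])),
    }
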