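"""Landmark identification in the first frame.

Small bright cell bodies (~15 um radius) are emphasised by a
difference-of-Gaussians bandpass, every window position of the first
frame is scored by its Pearson correlation with a fixed 2-D Gaussian
template, and the bimodal correlation distribution is split with a
two-component Gaussian mixture model.  Overlapping candidate windows
over the same blob are resolved by keeping the most centrally placed
one, and the retained landmarks get sub-pixel frame-1 centres from a
Gaussian fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.mixture import GaussianMixture

from .tracking import fit_gaussian

log = logging.getLogger(__name__)

# Fall back to a plain correlation threshold when the two mixture means
# are closer than this (effectively unimodal distribution).
_GMM_MEAN_SEPARATION = 0.1
_FALLBACK_THRESHOLD = 0.5


class DetectionError(RuntimeError):
    """Raised when too few landmarks are retained."""


@dataclass
class Landmark:
    """One trackable blob found in frame 1.

    ``window_origin`` is the integer (row, col) of the top-left pixel of
    the (2r+1) x (2r+1) tracking window; ``centre0`` the sub-pixel blob
    centre in frame 1, image coordinates.
    """

    id: int
    window_origin: tuple[int, int]
    centre0: tuple[float, float]
    correlation: float
    r: int
    fit_A: float = 0.0
    fit_B: float = 1.0
    fit_sigma: float = 2.0
    fit_residual: float = 0.0


def gaussian_template(r: int) -> np.ndarray:
    """The fixed detection template on a (2r+1) x (2r+1) window.

    An isotropic Gaussian with zero offset, centred on the window
    centre, sigma = (2r+1)/3, normalised to unit sum.
    """
    size = 2 * r + 1
    sigma = size / 3.0
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    g = np.exp(-((rows - r) ** 2 + (cols - r) ** 2) / (2.0 * sigma**2))
    return g / g.sum()


def bandpass_frame(frame: np.ndarray, small: float, large: float) -> np.ndarray:
    """Difference-of-Gaussians bandpass, passing structures small..large px.

    Smooths with sigma = small/4 and subtracts a smooth with
    sigma = large/4 (reading the band limits as structure diameters,
    sigma ~ diameter/4); the result is mean-centred so a constant frame
    maps to zero.
    """
    frame = np.asarray(frame, dtype=float)
    if not 0 < small < large:
        raise ValueError("need 0 < small < large")
    if large > min(frame.shape):
        raise ValueError("large band exceeds frame size")
    lo = ndimage.gaussian_filter(frame, small / 4.0)
    hi = ndimage.gaussian_filter(frame, large / 4.0)
    out = lo - hi
    return out - out.mean()


def correlate_windows(filtered: np.ndarray, r: int) -> np.ndarray:
    """Pearson correlation of every (2r+1)^2 window with the template.

    Each window is normalised to unit sum before comparison, which
    leaves the correlation magnitude unchanged and sets its sign to that
    of the window sum.  Zero-variance windows get correlation 0 (they
    cannot be landmarks); border positions where the window overhangs
    the frame are NaN.  The value at (i, j) scores the window centred on
    pixel (i, j).
    """
    filtered = np.asarray(filtered, dtype=float)
    size = 2 * r + 1
    if min(filtered.shape) <= size:
        raise ValueError("frame must be larger than the window")
    template = gaussian_template(r)
    n = size * size
    t_mean = template.mean()
    t_std = template.std()

    mean_w = ndimage.uniform_filter(filtered, size, mode="constant")
    mean_w2 = ndimage.uniform_filter(filtered**2, size, mode="constant")
    # correlate = sum over window of W * T, centred
    mean_wt = ndimage.correlate(filtered, template, mode="constant") / n
    var_w = np.maximum(mean_w2 - mean_w**2, 0.0)
    std_w = np.sqrt(var_w)

    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (mean_wt - mean_w * t_mean) / (std_w * t_std)
    corr[std_w == 0] = 0.0
    corr = np.clip(corr, -1.0, 1.0)
    # sum-normalisation flips the sign for negative-sum windows
    corr *= np.sign(mean_w) + (mean_w == 0)

    corr[:r, :] = np.nan
    corr[-r:, :] = np.nan
    corr[:, :r] = np.nan
    corr[:, -r:] = np.nan
    return corr


def _split_correlations(values: np.ndarray, seed: int) -> float:
    """Threshold separating the landmark / non-landmark correlation modes.

    Fits a two-component 1-D Gaussian mixture; returns the correlation
    value above which the posterior of the higher-mean component exceeds
    0.5.  Falls back to a fixed threshold when the fitted means are
    indistinguishable.
    """
    gmm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
    gmm.fit(values.reshape(-1, 1))
    means = gmm.means_.ravel()
    hi = int(np.argmax(means))
    if abs(means[1] - means[0]) < _GMM_MEAN_SEPARATION:
        warnings.warn(
            "correlation distribution unimodal; falling back to fixed "
            f"threshold {_FALLBACK_THRESHOLD}", stacklevel=3)
        return _FALLBACK_THRESHOLD
    # posterior is monotone in the correlation beyond the crossing point;
    # locate the crossing on a fine grid between the two means
    grid = np.linspace(means.min(), means.max(), 2048).reshape(-1, 1)
    post = gmm.predict_proba(grid)[:, hi]
    above = np.nonzero(post > 0.5)[0]
    if len(above) == 0:
        return float(means[hi])
    return float(grid[above[0], 0])


def select_landmarks(filtered: np.ndarray,
                     raw: np.ndarray,
                     r: int,
                     seed: int = 0,
                     min_landmarks: int = 3) -> list[Landmark]:
    """Pick trackable landmarks from the first frame.

    Parameters
    ----------
    filtered
        Bandpassed first frame (used for the correlation scan).
    raw
        Raw first frame (the sub-pixel centre is fitted on the raw
        data, which is what tracking later fits frame by frame).
    r
        Window half-size.

    Windows assigned to the higher-correlation mixture component are
    candidates; each is fitted with the Gaussian model, and among
    mutually overlapping windows (rectangles sharing at least one
    pixel) only the one whose fitted centre is nearest its window
    centre survives, with ties broken by higher correlation then lower
    scan order.  Candidates whose fitted centres coincide within r px
    are treated as duplicates of one blob.
    """
    corr = correlate_windows(filtered, r)
    values = corr[np.isfinite(corr)]
    if values.size == 0:
        raise DetectionError("no valid window positions")
    threshold = _split_correlations(values, seed)

    # every above-threshold window is a candidate in principle, but a
    # window that is not a correlation local maximum within the window
    # footprint always loses the centrality contest to a neighbour, so
    # only local maxima are fitted
    cmap = np.where(np.isfinite(corr), corr, -np.inf)
    size_footprint = 2 * r + 1
    local_max = cmap == ndimage.maximum_filter(cmap, size=size_footprint)
    cand_rows, cand_cols = np.nonzero((cmap > threshold) & local_max)
    size = 2 * r + 1
    height, width = filtered.shape
    template_sigma = size / 3.0

    candidates = []  # (centrality, -corr, order, origin, centre, corr, fit)
    for order, (i, j) in enumerate(zip(cand_rows, cand_cols)):
        origin = (int(i) - r, int(j) - r)
        window = raw[origin[0]:origin[0] + size, origin[1]:origin[1] + size]
        fit = fit_gaussian(window, (float(window.min()),
                                    float(np.ptp(window)),
                                    template_sigma, r, r))
        if not fit.converged:
            continue
        # a fitted centre pinned at the window boundary is not an
        # interior optimum; such candidates are ringing or edge artefacts
        if not (0.05 < fit.row < size - 1.05 and 0.05 < fit.col < size - 1.05):
            continue
        centre = (origin[0] + fit.row, origin[1] + fit.col)
        centrality = float(np.hypot(fit.row - r, fit.col - r))
        candidates.append((centrality, -float(corr[i, j]), order,
                           origin, centre, float(corr[i, j]), fit))

    candidates.sort(key=lambda c: c[:3])
    kept: list[tuple] = []
    for cand in candidates:
        origin, centre = cand[3], cand[4]
        clash = False
        for k in kept:
            ko, kc = k[3], k[4]
            window_overlap = (abs(origin[0] - ko[0]) <= 2 * r
                              and abs(origin[1] - ko[1]) <= 2 * r)
            same_blob = np.hypot(centre[0] - kc[0], centre[1] - kc[1]) <= r
            if window_overlap or same_blob:
                clash = True
                break
        if not clash:
            kept.append(cand)

    # stable ids in raster order of the window origin
    kept.sort(key=lambda c: c[3])
    landmarks = [
        Landmark(id=idx, window_origin=c[3], centre0=c[4],
                 correlation=c[5], r=r,
                 fit_A=c[6].A, fit_B=c[6].B, fit_sigma=c[6].sigma,
                 fit_residual=c[6].residual)
        for idx, c in enumerate(kept)
    ]
    if len(landmarks) < min_landmarks:
        raise DetectionError(
            f"only {len(landmarks)} landmarks retained "
            f"(minimum {min_landmarks})")
    log.info("detected %d landmarks (threshold %.3f)", len(landmarks), threshold)
    return landmarks


def detect_landmarks(frame: np.ndarray,
                     r: int = 3,
                     bandpass_small: float = 10.0,
                     bandpass_large: float = 18.0,
                     seed: int = 0,
                     min_landmarks: int = 3) -> list[Landmark]:
    """Bandpass the first frame and select landmarks (convenience wrapper)."""
    filtered = bandpass_frame(frame, bandpass_small, bandpass_large)
    return select_landmarks(filtered, np.asarray(frame, dtype=float), r,
                            seed=seed, min_landmarks=min_landmarks)
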