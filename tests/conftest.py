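"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import myotrack as mt
from myotrack.detection import Landmark
from myotrack.synthetic import generate_movie, preset
from myotrack.tracking import fit_gaussian


def render_blob_frame(shape, centres, amps, sigma, background=0.0):
    """Analytic frame of isotropic Gaussian blobs on a flat background."""
    H, W = shape
    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    frame = np.full((H, W), float(background))
    for (cr, cc), a in zip(np.atleast_2d(centres), np.atleast_1d(amps)):
        frame += a * np.exp(-((rows - cr) ** 2 + (cols - cc) ** 2)
                            / (2.0 * sigma**2))
    return frame


def truth_landmarks(stack, truth, r=3):
    """Landmark objects seeded from ground-truth frame-1 centres.

    Bypasses detection so filter tests can match landmark ids to the
    generator's blob indices directly.
    """
    lms = []
    H, W = stack.shape
    size = 2 * r + 1
    for i, (cr, cc) in enumerate(truth.centres0_px):
        origin = (int(round(cr)) - r, int(round(cc)) - r)
        if not (0 <= origin[0] and 0 <= origin[1]
                and origin[0] + size <= H and origin[1] + size <= W):
            continue
        win = stack.frames[0, origin[0]:origin[0] + size,
                           origin[1]:origin[1] + size]
        fit = fit_gaussian(win, (float(win.min()), float(np.ptp(win)),
                                 size / 3.0, cr - origin[0], cc - origin[1]))
        lms.append(Landmark(i, origin,
                            (origin[0] + fit.row, origin[1] + fit.col),
                            1.0, r, fit.A, fit.B, fit.sigma, fit.residual))
    return lms


def small_spec(seed=1, **overrides):
    """A fast-to-process contracting movie for pipeline-level tests."""
    base = dict(shape=(64, 64), n_frames=12, landmark_spacing_um=40.0,
                motion_onset_s=2.0, motion_rise_s=5.0, motion_fall_s=4.0,
                ca_lead_s=1.0, ca_rise_s=2.0, ca_hold_s=3.0, ca_fall_s=3.0,
                global_peak_disp_um=30.0)
    base.update(overrides)
    return preset("contracting", seed=seed, **base)


@pytest.fixture(scope="session")
def contracting_run():
    """Full pipeline on the default contracting fixture (seed 1)."""
    stack, truth = generate_movie(preset("contracting", seed=1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = mt.process_stack(stack, kinematics=True)
    return stack, truth, result


@pytest.fixture(scope="session")
def zero_motion_run():
    """Full pipeline on the noiseless zero-motion fixture (seed 1)."""
    stack, truth = generate_movie(preset("zero_motion", seed=1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = mt.process_stack(stack, kinematics=False)
    return stack, truth, result
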