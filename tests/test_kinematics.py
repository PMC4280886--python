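"""ROI fluorescence signals and local contraction measures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myotrack.correction import CorrectedStack
from myotrack.field import DisplacementField
from myotrack.kinematics import (contraction_field, quad_area, roi_signal,
                                 signal_timing)

UNIT_SQUARE = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0], [1.0, 0.0]])


def _corrected(frames, mask=None, px=1.0, dt=1.0):
    frames = np.asarray(frames, dtype=float)
    if mask is None:
        mask = np.ones(frames.shape, dtype=bool)
    return CorrectedStack(frames, mask, px, dt)


class TestQuadArea:
    def test_unit_square(self):
        area, degenerate = quad_area(UNIT_SQUARE)
        assert area == 1.0 and not degenerate

    def test_scaled_square_gives_19_percent_contraction(self):
        area, _ = quad_area(0.9 * UNIT_SQUARE)
        assert np.isclose(1.0 - area, 0.19, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(theta=st.floats(0.0, 2 * np.pi))
    def test_rotation_invariance(self, theta):
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        area, _ = quad_area(UNIT_SQUARE @ R.T)
        assert np.isclose(area, 1.0, atol=1e-9)

    def test_shoelace_additivity(self):
        # split a quad along a diagonal midline: parts sum to the whole
        quad = np.array([[0.0, 0.0], [0.3, 2.1], [2.4, 2.6], [2.0, 0.2]])
        mid_a = 0.5 * (quad[0] + quad[1])
        mid_b = 0.5 * (quad[3] + quad[2])
        lower = np.array([quad[0], mid_a, mid_b, quad[3]])
        upper = np.array([mid_a, quad[1], quad[2], mid_b])
        whole, _ = quad_area(quad)
        assert abs(quad_area(lower)[0] + quad_area(upper)[0] - whole) < 1e-9

    def test_affine_determinant(self):
        M = np.array([[0.8, 0.1], [-0.2, 1.1]])
        area, _ = quad_area(UNIT_SQUARE @ M.T)
        assert np.isclose(area, abs(np.linalg.det(M)), atol=1e-12)

    def test_bowtie_flagged(self):
        bowtie = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        _, degenerate = quad_area(bowtie)
        assert degenerate

    def test_shape_checked(self):
        with pytest.raises(ValueError):
            quad_area(np.zeros((3, 2)))


class TestContractionField:
    def _affine_field(self, M, n=3, shape=(40, 40), px=1.0):
        rows, cols = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
        x = np.stack([rows, cols], axis=-1)
        D_full = x @ (M - np.eye(2)).T
        D = np.zeros((n, *shape, 2))
        for t in range(1, n):
            D[t] = D_full * t / (n - 1)
        return DisplacementField(D, 10.0, px, 1.0)

    def test_affine_contraction_exact(self):
        M = np.array([[0.9, 0.0], [0.0, 0.9]])
        grid = contraction_field(self._affine_field(M), spacing_um=5.0)
        assert np.allclose(grid.dK_over_K0[0], 0.0, atol=1e-12)
        assert np.allclose(grid.dK_over_K0[-1], 1.0 - np.linalg.det(M),
                           atol=1e-9)
        assert not grid.degenerate.any()

    def test_rotation_gives_zero_contraction(self):
        # n=2: linear interpolation of a rotation's displacement is not
        # itself a rotation, so only the end state is area-preserving
        theta = 0.25
        M = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        grid = contraction_field(self._affine_field(M, n=2), spacing_um=5.0)
        assert np.allclose(grid.dK, 0.0, atol=1e-9)

    def test_K0_matches_spacing(self):
        f = DisplacementField(np.zeros((2, 30, 30, 2)), 10.0, 2.0, 1.0)
        grid = contraction_field(f, spacing_um=10.0)
        assert np.isclose(grid.K0, 100.0)
        assert np.allclose(grid.K, 100.0)

    def test_spacing_floor(self):
        f = DisplacementField(np.zeros((2, 30, 30, 2)), 10.0, 2.0, 1.0)
        with pytest.raises(ValueError, match="at least 2"):
            contraction_field(f, spacing_um=2.0)

    def test_cell_trace(self):
        M = np.array([[0.95, 0.0], [0.0, 0.95]])
        grid = contraction_field(self._affine_field(M, n=4), spacing_um=5.0)
        trace = grid.cell_trace(1, 1)
        assert trace.shape == (4,)
        assert np.all(np.diff(trace) > 0)   # monotone ramp


class TestROISignal:
    def test_constant_movie(self):
        c = _corrected(np.full((5, 10, 10), 40.0))
        sig = roi_signal(c, np.ones((10, 10), dtype=bool))
        assert np.allclose(sig.F, 40.0)
        assert np.allclose(sig.dFF0, 0.0)

    def test_known_transient_recovered(self):
        profile = np.array([1.0, 1.0, 1.5, 2.0, 1.2, 1.0])
        frames = 30.0 * profile[:, None, None] * np.ones((6, 8, 8))
        sig = roi_signal(_corrected(frames), np.ones((8, 8), dtype=bool),
                         baseline_method="first_frame")
        assert np.allclose(sig.F0, 30.0)
        assert np.allclose(sig.dFF0, profile - 1.0)

    def test_lowest_decile_baseline(self):
        F_t = np.array([10.0] + [50.0] * 9)
        frames = F_t[:, None, None] * np.ones((10, 6, 6))
        sig = roi_signal(_corrected(frames), np.ones((6, 6), dtype=bool))
        assert np.isclose(sig.F0, 10.0)

    def test_window_baseline(self):
        F_t = np.array([10.0, 20.0, 80.0, 80.0])
        frames = F_t[:, None, None] * np.ones((4, 6, 6))
        sig = roi_signal(_corrected(frames), np.ones((6, 6), dtype=bool),
                         baseline_method="window", baseline_window=(0, 2))
        assert np.isclose(sig.F0, 15.0)

    def test_masked_pixels_excluded(self):
        frames = np.ones((3, 6, 6))
        frames[:, :3] = 100.0
        mask = np.ones((3, 6, 6), dtype=bool)
        mask[:, :3] = False   # the bright half is invalid
        sig = roi_signal(_corrected(frames, mask), np.ones((6, 6), dtype=bool))
        assert np.allclose(sig.F, 1.0)

    def test_polygon_roi(self):
        frames = np.zeros((2, 20, 20))
        frames[:, 5:10, 5:10] = 50.0
        poly = np.array([[4.5, 4.5], [4.5, 9.5], [9.5, 9.5], [9.5, 4.5]])
        sig = roi_signal(_corrected(frames), poly,
                         baseline_method="first_frame")
        assert np.isclose(sig.F[0], 50.0)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            roi_signal(_corrected(np.ones((2, 6, 6))),
                       np.zeros((6, 6), dtype=bool))

    def test_unknown_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            roi_signal(_corrected(np.ones((2, 6, 6))),
                       np.ones((6, 6), dtype=bool), baseline_method="bogus")


class TestSignalTiming:
    def test_linear_ramp(self):
        # 0 -> 1 over 10 s: 20-80% crossings at 2 s and 8 s -> rise 6 s
        t = np.linspace(0, 10, 101)
        timing = signal_timing(t / 10.0, t)
        assert np.isclose(timing.rise_s, 6.0, atol=1e-9)
        assert np.isnan(timing.fall_s)   # no falling phase

    def test_symmetric_bump(self):
        t = np.linspace(0, 20, 201)
        trace = np.exp(-((t - 10.0) ** 2) / (2 * 2.0**2))
        timing = signal_timing(trace, t)
        assert np.isclose(timing.rise_s, timing.fall_s, atol=1e-6)
        assert timing.rise_s > 0

    def test_flat_trace_is_nan(self):
        t = np.arange(10.0)
        timing = signal_timing(np.zeros(10), t)
        assert np.isnan(timing.rise_s) and np.isnan(timing.fall_s)
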