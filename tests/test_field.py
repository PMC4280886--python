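"""Displacement-field extrapolation and length-scale optimization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myotrack.field import (build_field, exponential_kernel, gaussian_kernel,
                            landmark_displacements, optimize_lambda,
                            weighted_displacement)
from myotrack.tracking import Trajectory


def _traj(i, positions):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return Trajectory(i, positions, np.zeros((n, 3)), np.zeros(n))


class TestKernels:
    def test_gaussian_values(self):
        assert np.isclose(gaussian_kernel(np.array([10.0]), 10.0)[0],
                          np.exp(-1.0))
        assert gaussian_kernel(np.array([0.0]), 5.0)[0] == 1.0

    def test_limits(self):
        phi = np.array([0.0, 3.0, 7.0])
        assert np.array_equal(gaussian_kernel(phi, np.inf), np.ones(3))
        assert np.array_equal(gaussian_kernel(phi, 0.0), [1.0, 0.0, 0.0])
        assert np.array_equal(exponential_kernel(phi, np.inf), np.ones(3))
        assert np.array_equal(exponential_kernel(phi, 0.0), [1.0, 0.0, 0.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(phi=st.floats(0.0, 1e3), lam=st.floats(1e-3, 1e6))
    def test_gaussian_in_unit_interval(self, phi, lam):
        w = gaussian_kernel(np.array([phi]), lam)[0]
        assert 0.0 <= w <= 1.0


class TestWeightedDisplacement:
    # hand-computed oracle: landmarks at distance 10 and 20 um with
    # displacements (1,0) and (3,0), lambda = 10 um:
    # w = e^-1, e^-4 -> D = (e^-1 + 3 e^-4) / (e^-1 + e^-4) = 1.09485...
    def test_two_landmark_oracle(self):
        pos0 = np.array([[0.0, 10.0], [0.0, 20.0]])
        disp = np.array([[[1.0, 0.0]], [[3.0, 0.0]]])   # (L, 1 frame, 2)
        out = weighted_displacement((0.0, 0.0), pos0, disp, 10.0, frame=0)
        expect = (np.exp(-1) + 3 * np.exp(-4)) / (np.exp(-1) + np.exp(-4))
        assert np.isclose(out[0], expect, atol=1e-12)
        assert np.isclose(expect, 1.0948503, atol=1e-6)
        assert out[1] == 0.0

    def test_infinite_lambda_is_mean(self):
        rng = np.random.default_rng(0)
        pos0 = rng.uniform(0, 50, size=(6, 2))
        disp = rng.normal(size=(6, 4, 2))
        out = weighted_displacement((10.0, 10.0), pos0, disp, np.inf)
        assert np.allclose(out, disp.mean(axis=0), atol=1e-12)

    def test_zero_lambda_is_nearest(self):
        pos0 = np.array([[0.0, 0.0], [10.0, 10.0]])
        disp = np.array([[[1.0, 1.0]], [[5.0, 5.0]]])
        out = weighted_displacement((2.0, 2.0), pos0, disp, 0.0, frame=0)
        assert np.array_equal(out, [1.0, 1.0])
        out = weighted_displacement((9.0, 9.0), pos0, disp, 0.0, frame=0)
        assert np.array_equal(out, [5.0, 5.0])

    def test_at_landmark_small_lambda_returns_own_displacement(self):
        pos0 = np.array([[5.0, 5.0], [40.0, 40.0]])
        disp = np.array([[[2.0, -1.0]], [[7.0, 3.0]]])
        out = weighted_displacement((5.0, 5.0), pos0, disp, 1.0, frame=0)
        assert np.allclose(out, [2.0, -1.0], atol=1e-9)

    def test_invalid_frames_excluded(self):
        pos0 = np.array([[0.0, 0.0], [4.0, 0.0]])
        disp = np.array([[[1.0, 0.0]], [[9.0, 0.0]]])
        valid = np.array([[True], [False]])
        out = weighted_displacement((2.0, 0.0), pos0, disp, 10.0,
                                    valid=valid, frame=0)
        assert np.allclose(out, [1.0, 0.0])


class TestBuildField:
    def test_zero_displacements_give_zero_field(self):
        pos0 = np.array([[2.0, 2.0], [10.0, 12.0], [14.0, 4.0]])
        disp = np.zeros((3, 3, 2))
        f = build_field(pos0, disp, 8.0, (16, 16))
        assert np.allclose(f.D_p, 0.0)

    def test_uniform_displacements_reproduced_everywhere(self):
        pos0 = np.array([[2.0, 2.0], [10.0, 12.0], [14.0, 4.0]])
        disp = np.tile(np.array([1.5, -0.5]), (3, 2, 1))
        f = build_field(pos0, disp, 8.0, (16, 16))
        assert np.allclose(f.D_p[1], [1.5, -0.5], atol=1e-12)

    def test_requires_positive_lambda(self):
        with pytest.raises(ValueError):
            build_field(np.zeros((2, 2)), np.zeros((2, 2, 2)), 0.0, (8, 8))

    def test_field_methods(self):
        pos0 = np.array([[2.0, 2.0], [6.0, 6.0]])
        disp = np.zeros((2, 3, 2))
        disp[:, 1] = [1.0, 0.0]
        disp[:, 2] = [2.0, 0.0]
        f = build_field(pos0, disp, 5.0, (8, 8), frame_interval_s=2.0)
        assert f.n_frames == 3 and f.shape == (8, 8)
        pos = f.positions()
        assert np.allclose(pos[2, :, :, 0] - pos[0, :, :, 0], 2.0)
        v = f.velocity()
        assert np.allclose(v[1, :, :, 0], 0.5)   # 1 px per 2 s


class TestLandmarkDisplacements:
    def test_nan_handling(self):
        t0 = _traj(0, [[1.0, 1.0], [2.0, 1.0], [np.nan, np.nan]])
        t1 = _traj(1, [[5.0, 5.0], [5.0, 6.0], [5.0, 7.0]])
        pos0, disp, valid = landmark_displacements([t0, t1])
        assert np.array_equal(pos0, [[1.0, 1.0], [5.0, 5.0]])
        assert valid.tolist() == [[True, True, False], [True, True, True]]
        assert np.all(np.isfinite(disp))


class TestOptimizeLambda:
    def test_needs_two_landmarks(self):
        with pytest.raises(ValueError):
            optimize_lambda(np.zeros((1, 2)), np.zeros((1, 2, 2)),
                            np.array([1.0, 10.0]))

    def test_two_landmarks_flat_curve_warns(self):
        # with two landmarks the LOO prediction is always "the other one",
        # independent of lambda -> flat error curve, minimum at grid edge
        pos0 = np.array([[0.0, 0.0], [10.0, 0.0]])
        disp = np.array([[[1.0, 0.0]], [[2.0, 0.0]]])
        with pytest.warns(UserWarning, match="grid edge"):
            res = optimize_lambda(pos0, disp, np.geomspace(1, 100, 8))
        assert res.at_boundary
        assert np.allclose(res.mean_error_um, res.mean_error_um[0])

    def test_interior_minimum_refined(self):
        # kernel-generated field: error curve has an interior minimum
        rng = np.random.default_rng(5)
        pos0 = rng.uniform(0, 100, size=(60, 2))
        centre = np.array([50.0, 50.0])
        d = pos0 - centre
        u = d * np.exp(-np.sum(d**2, axis=1, keepdims=True) / (2 * 20.0**2))
        u = 5.0 * u / np.abs(u).max()
        disp = u[:, None, :] * np.linspace(0, 1, 5)[None, :, None]
        disp = disp + rng.normal(scale=0.05, size=disp.shape)
        res = optimize_lambda(pos0, disp, np.geomspace(2, 1024, 24))
        assert not res.at_boundary
        grid_argmin = res.lambda_grid[np.argmin(res.mean_error_um)]
        lo, hi = grid_argmin / 2, grid_argmin * 2
        assert lo < res.lambda_c < hi
        assert np.isclose(res.normalized_error.max(), 1.0)
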