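"""Choosing the extrapolation length scale lambda by leave-one-out.

The dense displacement field is a Gaussian-kernel weighted average of
landmark displacements, w = exp(-(phi/lambda)^2).  lambda controls how
far each landmark's influence reaches: lambda -> 0 degenerates to
nearest-landmark (Voronoi) extrapolation, lambda -> inf to the uniform
mean over all landmarks.  The pipeline chooses lambda_c by minimizing
the leave-one-out (LOO) prediction error of landmark displacements.

This script shows (a) the LOO error curve on a tracked recording and
(b) that the chosen lambda_c tracks the true heterogeneity scale L of
the underlying deformation.
"""

import warnings

import numpy as np

import myotrack as mt
from myotrack.synthetic import _WarpModel, generate_movie, preset

GRID = np.geomspace(2.0, 1024.0, 24)

# --- (a) LOO curve on a tracked recording --------------------------------
spec = preset("contracting", seed=1)
stack, _ = generate_movie(spec)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    lms = mt.detect_landmarks(stack.frames[0])
    trajs = mt.track_all(stack, lms)
    kept, _ = mt.apply_filters(trajs)
pos0, disp, valid = mt.landmark_displacements(kept)
res = mt.optimize_lambda(pos0, disp, GRID, stack.pixel_width_um, valid=valid)

print("lambda (um)   LOO error (um)")
for lam, err in zip(res.lambda_grid[::3], res.mean_error_um[::3]):
    bar = "#" * int(round(40 * err / res.mean_error_um.max()))
    print(f"  {lam:8.1f}   {err:8.3f}  {bar}")
print(f"chosen lambda_c = {res.lambda_c:.1f} um "
      f"(at_boundary={res.at_boundary})")

# --- (b) lambda_c tracks the generative heterogeneity scale L ------------
# Sample an analytic warp of known scale L at scattered landmarks, add
# tracking-level noise (0.15 px), and ask the estimator for lambda_c.
print("\ntrue scale L (um) -> estimated lambda_c (um)")
rng = np.random.default_rng(1)
pos_um = rng.uniform(0, 400, size=(300, 2))
centres = rng.uniform(0, 400, size=(40, 2))
amps = rng.choice([-1.0, 1.0], size=40)
profile = np.linspace(0, 1, 10)
for L in (20.0, 40.0, 80.0):
    warp = _WarpModel(centres, np.full(40, L), amps, profile)
    u = warp.spatial(pos_um)
    u *= 10.0 / np.max(np.linalg.norm(u, axis=1))
    d = (profile[:, None, None] * u[None]).transpose(1, 0, 2)
    d = d + rng.normal(scale=0.15, size=d.shape)
    est = mt.optimize_lambda(pos_um, d, GRID, pixel_width_um=1.0)
    print(f"  L = {L:5.0f}  ->  lambda_c = {est.lambda_c:6.1f}")
print("\nlambda_c rises with L: smoother tissue motion supports wider "
      "averaging.\nWhen L falls below the landmark spacing the optimum "
      "drifts to large lambda\n(uniform averaging) because the "
      "heterogeneity is not sampled -- an\nidentifiability limit, not an "
      "estimator defect.")
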